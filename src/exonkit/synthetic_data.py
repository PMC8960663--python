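"""Synthetic genomes, splicing-event tables, count matrices and signal tracks.

Every generator plants known structure so each analysis stage has a
ground-truth recovery test:

* a genome of cassette-exon genes (two transcripts per gene: one with and
  one without the middle alternative exon) whose exon bodies are drawn at
  class-specific GC targets against a uniform-GC background;
* per-replicate differential-inclusion calls with Bayes factors, including
  discordant decoys (opposite delta-PSI between replicates) and redundant
  short exon forms sharing a splice-site boundary with a true exon;
* optional splice-site trinucleotide planting.  When a motif is configured
  its occurrence count is *derandomized*: exactly ``round(rate * n)`` target
  exons receive the motif, non-designated sites are resampled to exclude
  it, and background exons receive the motif at its expected natural rate
  for the background GC — so the planted enrichment ratio is recovered
  without binomial noise on top of it;
* negative-binomial count matrices with planted per-sample size factors and
  an overdispersed, group-shifted highly-variable-gene subset;
* a nucleosome-occupancy track: baseline 1.0, Gaussian bumps centered on
  included exons, and block-wise coverage gaps.

One global seed drives independent named sub-streams (genome, events,
counts, signal), so modules regenerate identically in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (ComparisonRecord, CountMatrix, ExonRecord,
                         GenomeSequence, GenomicInterval, SignalTrack,
                         reverse_complement, write_bed, write_bedgraph,
                         write_comparison_table, write_counts, write_fasta)

# class labels; together they partition the exon universe
LABEL_INCLUDED = "included"
LABEL_SKIPPED = "skipped"
LABEL_NULL = "null"
LABEL_DISCORDANT = "discordant-decoy"
LABEL_REDUNDANT = "redundant-decoy"

_STREAMS = {"genome": 0, "events": 1, "counts": 2, "signal": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SimulationConfig:
    """All knobs of the generator; ranges are (low, high) inclusive."""

    seed: int = 0
    # genome architecture
    n_genes: int = 300
    exons_per_gene: Tuple[int, int] = (3, 5)
    exon_length: Tuple[int, int] = (80, 250)
    intron_length: Tuple[int, int] = (600, 1200)
    intergenic_gap: int = 1000
    max_chrom_length: int = 200_000_000
    # GC targets
    gc_exon_included: float = 0.65
    gc_exon_skipped: float = 0.45
    gc_background: float = 0.45
    # event-table parameters
    groups: Tuple[str, ...] = ("groupA", "groupB")
    n_replicates: int = 2
    included_fraction: float = 0.3
    skipped_fraction: float = 0.3
    discordant_fraction: float = 0.05
    redundant_form_fraction: float = 0.1
    delta_psi_mean: float = 0.3
    delta_psi_sd: float = 0.1
    bayes_factor_affected: Tuple[float, float] = (15.0, 1000.0)
    bayes_factor_null: Tuple[float, float] = (0.0, 5.0)
    # splice-site motif planting (None disables)
    acceptor_motif: Optional[str] = None
    acceptor_motif_rate: float = 0.0
    donor_motif: Optional[str] = None
    donor_motif_rate: float = 0.0
    # count matrices
    n_count_genes: int = 5000
    n_count_replicates: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    n_hvg: int = 100
    hvg_dispersion_multiplier: float = 20.0
    hvg_log2fc: float = 4.0
    size_factor_range: Tuple[float, float] = (0.5, 2.0)
    exon_count_mean: float = 50.0
    # signal track
    nucleosome_amplitude: float = 4.0
    nucleosome_width: float = 50.0
    signal_baseline: float = 1.0
    coverage_gap_fraction: float = 0.1
    gap_block_size: int = 100

    def __post_init__(self) -> None:
        fractions = {
            "gc_exon_included": self.gc_exon_included,
            "gc_exon_skipped": self.gc_exon_skipped,
            "gc_background": self.gc_background,
            "included_fraction": self.included_fraction,
            "skipped_fraction": self.skipped_fraction,
            "discordant_fraction": self.discordant_fraction,
            "redundant_form_fraction": self.redundant_form_fraction,
            "coverage_gap_fraction": self.coverage_gap_fraction,
            "acceptor_motif_rate": self.acceptor_motif_rate,
            "donor_motif_rate": self.donor_motif_rate,
        }
        for name, v in fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        alt_total = (self.included_fraction + self.skipped_fraction
                     + self.discordant_fraction)
        if alt_total > 1.0 + 1e-12:
            raise ValueError("class fractions sum to more than 1")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "bayes_factor_affected", "bayes_factor_null",
                     "size_factor_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons for an internal cassette exon")
        if self.exon_length[0] < 6:
            raise ValueError("exon_length low must be >= 6")
        for motif in (self.acceptor_motif, self.donor_motif):
            if motif is not None and (len(motif) != 3 or set(motif) - set("ACGT")):
                raise ValueError(f"motif must be a trinucleotide over ACGT: {motif!r}")

    # -- plain-text config files (key = value) -----------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if v is None:
                    text = "none"
                elif isinstance(v, tuple):
                    text = ",".join(str(x) for x in v)
                else:
                    text = str(v)
                fh.write(f"{f.name} = {text}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = _parse_config_value(key, raw, cls())
        return cls(**kwargs)


def _parse_config_value(key: str, raw: str, defaults: "SimulationConfig"):
    default = getattr(defaults, key)
    if raw.lower() == "none":
        return None
    if isinstance(default, tuple) or ("," in raw and key == "groups"):
        parts = [p.strip() for p in raw.split(",")]
        if key == "groups":
            return tuple(parts)
        elem = type(default[0]) if default else float
        return tuple(elem(p) for p in parts)
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


@dataclass
class SyntheticTruth:
    """Planted ground truth; one exon row per annotation record."""

    exons: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def exon_ids(self, label: Optional[str] = None,
                 role: Optional[str] = None) -> List[str]:
        df = self.exons
        if label is not None:
            df = df[df["label"] == label]
        if role is not None:
            df = df[df["role"] == role]
        return list(df["exon_id"])

    def intervals(self, label: Optional[str] = None,
                  role: Optional[str] = None) -> List[GenomicInterval]:
        df = self.exons
        if label is not None:
            df = df[df["label"] == label]
        if role is not None:
            df = df[df["role"] == role]
        return [GenomicInterval(r.chrom, r.start, r.end, r.strand)
                for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_CHROM = "chrS1"


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """n bases (uint8 codes) with independent per-base P(G or C) = gc."""
    is_gc = rng.random(n) < gc
    pick = rng.random(n) < 0.5
    out = np.empty(n, dtype=np.uint8)
    out[is_gc & pick] = ord("G")
    out[is_gc & ~pick] = ord("C")
    out[~is_gc & pick] = ord("A")
    out[~is_gc & ~pick] = ord("T")
    return out


def _tri_probability(tri: str, gc: float) -> float:
    """Probability of a trinucleotide under the independent per-base model."""
    p = 1.0
    for base in tri:
        p *= gc / 2.0 if base in "GC" else (1.0 - gc) / 2.0
    return p


def _write_site(chrom: np.ndarray, iv: GenomicInterval, side: str, tri: str) -> None:
    """Overwrite the exonic trinucleotide at the acceptor/donor side."""
    if side == "acceptor":
        genomic = tri if iv.strand == "+" else reverse_complement(tri)
        pos = iv.start if iv.strand == "+" else iv.end - 3
    else:
        genomic = tri if iv.strand == "+" else reverse_complement(tri)
        pos = iv.end - 3 if iv.strand == "+" else iv.start
    chrom[pos:pos + 3] = np.frombuffer(genomic.encode("ascii"), dtype=np.uint8)


def _read_site(chrom: np.ndarray, iv: GenomicInterval, side: str) -> str:
    if side == "acceptor":
        pos = iv.start if iv.strand == "+" else iv.end - 3
    else:
        pos = iv.end - 3 if iv.strand == "+" else iv.start
    s = chrom[pos:pos + 3].tobytes().decode("ascii")
    return s if iv.strand == "+" else reverse_complement(s)


def _sample_non_motif_tri(rng: np.random.Generator, gc: float, motif: str) -> str:
    bases = "ACGT"
    probs = np.array([gc / 2 if b in "GC" else (1 - gc) / 2 for b in bases])
    while True:
        tri = "".join(rng.choice(list(bases), size=3, p=probs))
        if tri != motif:
            return tri


def _plant_motif(chrom: np.ndarray, rng: np.random.Generator,
                 targets: List[GenomicInterval],
                 background: List[GenomicInterval],
                 side: str, motif: str, rate: float, gc_background: float,
                 planted_flags: Dict[tuple, bool]) -> None:
    """Derandomized planting: exact counts in targets, natural rate elsewhere."""
    natural = _tri_probability(motif, gc_background)
    for pool, r in ((targets, rate), (background, natural)):
        n = len(pool)
        if n == 0:
            continue
        m = int(round(r * n))
        chosen = set(rng.choice(n, size=m, replace=False)) if m else set()
        for i, iv in enumerate(pool):
            if i in chosen:
                _write_site(chrom, iv, side, motif)
                planted_flags[iv.key] = True
            elif _read_site(chrom, iv, side) == motif:
                _write_site(chrom, iv, side,
                            _sample_non_motif_tri(rng, gc_background, motif))


def simulate_genome(config: SimulationConfig) -> Tuple[GenomeSequence, List[ExonRecord], SyntheticTruth]:
    """Tile cassette-exon genes on one synthetic chromosome.

    Each gene carries two transcripts (with / without its middle exon); the
    middle exon's class is drawn from the configured fractions.  Redundant
    decoy exons overlap affected exons, share one transcription-orientation
    boundary and are strictly shorter than half of the parent.
    """
    rng = _rng(config.seed, "genome")
    gc_by_label = {
        LABEL_INCLUDED: config.gc_exon_included,
        LABEL_SKIPPED: config.gc_exon_skipped,
        LABEL_DISCORDANT: config.gc_background,
        LABEL_NULL: config.gc_background,
    }
    p_inc = config.included_fraction
    p_skip = config.skipped_fraction
    p_disc = config.discordant_fraction
    class_probs = np.array([p_inc, p_skip, p_disc,
                            max(0.0, 1.0 - p_inc - p_skip - p_disc)])
    class_probs = class_probs / class_probs.sum()
    class_names = [LABEL_INCLUDED, LABEL_SKIPPED, LABEL_DISCORDANT, LABEL_NULL]

    # layout pass
    layout = []  # per gene: (strand, [(start, end, label, role)], alt_index)
    cursor = 0
    for g in range(config.n_genes):
        cursor += config.intergenic_gap
        n_ex = int(rng.integers(config.exons_per_gene[0],
                                config.exons_per_gene[1] + 1))
        alt_idx = n_ex // 2
        strand = "+" if rng.random() < 0.5 else "-"
        label = class_names[int(rng.choice(4, p=class_probs))]
        exons = []
        for i in range(n_ex):
            length = int(rng.integers(config.exon_length[0],
                                      config.exon_length[1] + 1))
            exons.append((cursor, cursor + length))
            cursor += length
            if i < n_ex - 1:
                cursor += int(rng.integers(config.intron_length[0],
                                           config.intron_length[1] + 1))
        layout.append((strand, exons, alt_idx, label))
    cursor += config.intergenic_gap
    chrom_len = cursor
    if chrom_len > config.max_chrom_length:
        raise ValueError(
            f"gene layout needs {chrom_len} bp, exceeding the "
            f"{config.max_chrom_length} bp chromosome budget")

    chrom = _draw_bases(rng, chrom_len, config.gc_background)

    annotation: List[ExonRecord] = []
    truth_rows: List[dict] = []
    affected: List[GenomicInterval] = []
    others: List[GenomicInterval] = []

    for g, (strand, exons, alt_idx, alt_label) in enumerate(layout):
        gene_id = f"g{g + 1:04d}"
        tx_full, tx_skip = f"{gene_id}.t1", f"{gene_id}.t2"
        for i, (start, end) in enumerate(exons):
            is_alt = i == alt_idx
            label = alt_label if is_alt else LABEL_NULL
            gc_target = gc_by_label[label]
            if gc_target != config.gc_background:
                chrom[start:end] = _draw_bases(rng, end - start, gc_target)
            iv = GenomicInterval(_CHROM, start, end, strand)
            exon_id = f"{gene_id}.e{i + 1}"
            tx = frozenset([tx_full]) if is_alt else frozenset([tx_full, tx_skip])
            annotation.append(ExonRecord(iv, exon_id, gene_id, tx))
            row = {
                "exon_id": exon_id, "chrom": _CHROM, "start": start, "end": end,
                "strand": strand, "gene_id": gene_id,
                "role": "alternative" if is_alt else "constitutive",
                "label": label, "gc_target": gc_target, "expressed": True,
                "decoy_parent": "",
                "bump_center": (start + end) // 2 if label == LABEL_INCLUDED else -1,
            }
            truth_rows.append(row)
            if label in (LABEL_INCLUDED, LABEL_SKIPPED):
                affected.append(iv)
            else:
                others.append(iv)

    # redundant decoy exons overlapping affected exons
    n_decoys = int(round(config.redundant_form_fraction * len(affected)))
    decoy_rows: List[dict] = []
    if n_decoys:
        parents = rng.choice(len(affected), size=n_decoys, replace=False)
        for idx in sorted(parents):
            parent = affected[idx]
            parent_row = next(r for r in truth_rows
                              if (r["start"], r["end"]) == (parent.start, parent.end)
                              and r["chrom"] == parent.chrom)
            L = parent.length
            max_len = (L - 1) // 2  # strictly below 50% of the parent
            length = int(rng.integers(6, max(7, max_len + 1)))
            length = min(length, max_len)
            share_five = rng.random() < 0.5
            # boundary identity in transcription orientation
            if (parent.strand == "+") == share_five:
                start, end = parent.start, parent.start + length
            else:
                start, end = parent.end - length, parent.end
            iv = GenomicInterval(parent.chrom, start, end, parent.strand)
            exon_id = parent_row["exon_id"] + ".rf"
            annotation.append(ExonRecord(iv, exon_id, parent_row["gene_id"],
                                         frozenset()))
            decoy_rows.append({
                "exon_id": exon_id, "chrom": iv.chrom, "start": start, "end": end,
                "strand": iv.strand, "gene_id": parent_row["gene_id"],
                "role": "decoy", "label": LABEL_REDUNDANT,
                "gc_target": parent_row["gc_target"], "expressed": True,
                "decoy_parent": parent_row["exon_id"], "bump_center": -1,
            })
            others.append(iv)
    truth_rows.extend(decoy_rows)

    planted_acceptor: Dict[tuple, bool] = {}
    planted_donor: Dict[tuple, bool] = {}
    if config.acceptor_motif is not None:
        _plant_motif(chrom, rng, affected, others, "acceptor",
                     config.acceptor_motif, config.acceptor_motif_rate,
                     config.gc_background, planted_acceptor)
    if config.donor_motif is not None:
        _plant_motif(chrom, rng, affected, others, "donor",
                     config.donor_motif, config.donor_motif_rate,
                     config.gc_background, planted_donor)

    truth = pd.DataFrame(truth_rows)
    keys = list(zip(truth["chrom"], truth["start"], truth["end"], truth["strand"]))
    truth["acceptor_planted"] = [planted_acceptor.get(k, False) for k in keys]
    truth["donor_planted"] = [planted_donor.get(k, False) for k in keys]

    genome = GenomeSequence({_CHROM: chrom.tobytes().decode("ascii")})
    return genome, annotation, SyntheticTruth(exons=truth)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def simulate_events(truth: SyntheticTruth,
                    config: SimulationConfig) -> List[ComparisonRecord]:
    """Per-replicate differential-inclusion calls for every planted exon.

    Included/skipped exons get consistent-sign delta-PSI with high Bayes
    factors; null exons small consistent-sign shifts with low Bayes
    factors; discordant decoys alternate sign across replicates at high
    Bayes factors; redundant decoys inherit their parent's behaviour on
    their own (short) coordinates.
    """
    rng = _rng(config.seed, "events")

    def bf(low_high) -> float:
        lo, hi = low_high
        lo = max(lo, 1e-3)
        return float(np.exp(rng.uniform(np.log(lo), np.log(max(hi, lo)))))

    def magnitude(mean: float, sd: float) -> float:
        return abs(float(rng.normal(mean, sd))) + 1e-6

    parent_label = dict(zip(truth.exons["exon_id"], truth.exons["label"]))
    membership: Dict[str, np.ndarray] = {}
    records: List[ComparisonRecord] = []
    alt = truth.exons[truth.exons["role"].isin(["alternative", "decoy"])]
    for row in alt.itertuples(index=False):
        label = row.label
        if label == LABEL_REDUNDANT:
            label = parent_label.get(row.decoy_parent, LABEL_INCLUDED)
            if label not in (LABEL_INCLUDED, LABEL_SKIPPED):
                label = LABEL_INCLUDED
            effective = label
        else:
            effective = label
        iv = GenomicInterval(row.chrom, row.start, row.end, row.strand)
        # nonempty random subset of groups, same behaviour in each; a
        # redundant decoy is an alternate form of the same comparison, so
        # it appears in exactly its parent's groups
        if row.label == LABEL_REDUNDANT and row.decoy_parent in membership:
            member = membership[row.decoy_parent]
        else:
            member = rng.random(len(config.groups)) < 0.6
            if not member.any():
                member[int(rng.integers(len(config.groups)))] = True
        membership[row.exon_id] = member
        for gi, group in enumerate(config.groups):
            if not member[gi]:
                continue
            if effective == LABEL_INCLUDED:
                psi0 = float(rng.uniform(0.15, 0.45))
                sign, bf_range = 1.0, config.bayes_factor_affected
                mean, sd = config.delta_psi_mean, config.delta_psi_sd
            elif effective == LABEL_SKIPPED:
                psi0 = float(rng.uniform(0.55, 0.85))
                sign, bf_range = -1.0, config.bayes_factor_affected
                mean, sd = config.delta_psi_mean, config.delta_psi_sd
            elif effective == LABEL_DISCORDANT:
                psi0 = float(rng.uniform(0.3, 0.7))
                sign, bf_range = 1.0, config.bayes_factor_affected
                mean, sd = config.delta_psi_mean, config.delta_psi_sd
            else:  # null
                psi0 = float(rng.uniform(0.2, 0.8))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                bf_range = config.bayes_factor_null
                mean, sd = 0.0, 0.03
            for rep in range(1, config.n_replicates + 1):
                rep_sign = sign
                if effective == LABEL_DISCORDANT and rep % 2 == 0:
                    rep_sign = -sign
                d = rep_sign * magnitude(mean, sd)
                # truncate so both PSI values stay inside [0, 1]
                d = float(np.clip(d, -psi0 + 1e-6, 1.0 - psi0 - 1e-6))
                records.append(ComparisonRecord(
                    event_id=f"{row.exon_id}|{group}",
                    exon=iv, gene_id=row.gene_id, group=group, replicate=rep,
                    psi_control=psi0, psi_treatment=psi0 + d,
                    bayes_factor=bf(bf_range)))
    return records


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: np.ndarray) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + a*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = dispersion <= 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        n = 1.0 / dispersion[~tiny]
        p = n / (n + mean[~tiny])
        out[~tiny] = rng.negative_binomial(n, p)
    return out


def simulate_counts(config: SimulationConfig,
                    exons: Optional[Sequence[ExonRecord]] = None,
                    truth: Optional[SyntheticTruth] = None
                    ) -> Tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Gene- and exon-level count matrices with planted structure.

    Genes: negative binomial around lognormal base means scaled by planted
    per-sample size factors; a planted HVG subset gets its dispersion
    multiplied and a between-group mean shift (random direction per gene).
    Exons: expressed exons are guaranteed a nonzero count in every control
    sample.  Samples: ``control1..k`` then ``treated1..k``.
    """
    rng = _rng(config.seed, "counts")
    k = config.n_count_replicates
    sample_names = ([f"control{i + 1}" for i in range(k)]
                    + [f"treated{i + 1}" for i in range(k)])
    group_of = {s: ("control" if s.startswith("control") else "treated")
                for s in sample_names}
    sf = rng.uniform(config.size_factor_range[0], config.size_factor_range[1],
                     size=len(sample_names))

    n = config.n_count_genes
    gene_ids = [f"cg{i + 1:05d}" for i in range(n)]
    base_mean = np.exp(rng.normal(np.log(config.nb_mean), 1.0, size=n))
    hvg_idx = np.sort(rng.choice(n, size=min(config.n_hvg, n), replace=False)) \
        if config.n_hvg > 0 else np.array([], dtype=int)
    hvg_mask = np.zeros(n, dtype=bool)
    hvg_mask[hvg_idx] = True
    shift_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    dispersion = np.where(hvg_mask,
                          config.nb_dispersion * config.hvg_dispersion_multiplier,
                          config.nb_dispersion)

    counts = np.empty((n, len(sample_names)), dtype=np.int64)
    half = config.hvg_log2fc / 2.0
    for j, sample in enumerate(sample_names):
        direction = 1.0 if group_of[sample] == "treated" else -1.0
        shift = np.where(hvg_mask, 2.0 ** (direction * shift_sign * half), 1.0)
        mu = base_mean * shift * sf[j]
        counts[:, j] = _nb_draw(rng, mu, dispersion)
    gene_matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids,
                                           columns=sample_names),
                              groups=group_of)

    # exon-level counts
    if exons is not None:
        exon_ids = [e.exon_id for e in exons]
    else:
        exon_ids = [f"ex{i + 1:05d}" for i in range(2000)]
    expressed = np.ones(len(exon_ids), dtype=bool)
    if truth is not None and not truth.exons.empty:
        flag = dict(zip(truth.exons["exon_id"], truth.exons["expressed"]))
        expressed = np.array([bool(flag.get(e, True)) for e in exon_ids])
    exon_mean = np.exp(rng.normal(np.log(config.exon_count_mean), 1.0,
                                  size=len(exon_ids)))
    exon_counts = np.empty((len(exon_ids), len(sample_names)), dtype=np.int64)
    for j, sample in enumerate(sample_names):
        exon_counts[:, j] = _nb_draw(rng, exon_mean * sf[j],
                                     np.full(len(exon_ids), config.nb_dispersion))
        if group_of[sample] == "control":
            exon_counts[expressed, j] = np.maximum(exon_counts[expressed, j], 1)
    exon_matrix = CountMatrix(pd.DataFrame(exon_counts, index=exon_ids,
                                           columns=sample_names),
                              groups=group_of)

    genes_df = pd.DataFrame({"gene_id": gene_ids, "hvg": hvg_mask,
                             "base_mean": base_mean,
                             "shift_sign": shift_sign})
    replicates = list(range(1, k + 1)) * 2
    samples_df = pd.DataFrame({"sample": sample_names,
                               "group": [group_of[s] for s in sample_names],
                               "replicate": replicates,
                               "size_factor": sf})
    out_truth = SyntheticTruth(
        exons=truth.exons if truth is not None else pd.DataFrame(),
        genes=genes_df, samples=samples_df)
    return gene_matrix, exon_matrix, out_truth


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------

def simulate_signal(annotation: Sequence[ExonRecord], truth: SyntheticTruth,
                    config: SimulationConfig) -> SignalTrack:
    """Nucleosome-occupancy-like track over the synthetic chromosome(s).

    Baseline everywhere, plus a Gaussian bump (configured amplitude and
    width) centered on each exon with a planted bump; block-wise coverage
    gaps are *missing*, not zero.
    """
    rng = _rng(config.seed, "signal")
    chrom_ends: Dict[str, int] = {}
    for rec in annotation:
        iv = rec.interval
        chrom_ends[iv.chrom] = max(chrom_ends.get(iv.chrom, 0), iv.end)
    bumps = truth.exons[truth.exons["bump_center"] >= 0] if not truth.exons.empty \
        else pd.DataFrame(columns=["chrom", "bump_center"])

    data = {}
    for chrom in sorted(chrom_ends):
        length = chrom_ends[chrom] + config.intergenic_gap
        values = np.full(length, float(config.signal_baseline))
        width = config.nucleosome_width
        for row in bumps[bumps["chrom"] == chrom].itertuples(index=False):
            c = int(row.bump_center)
            lo = max(0, int(c - 4 * width))
            hi = min(length, int(c + 4 * width) + 1)
            x = np.arange(lo, hi)
            values[lo:hi] += config.nucleosome_amplitude * np.exp(
                -((x - c) ** 2) / (2.0 * width ** 2))
        covered = np.ones(length, dtype=bool)
        n_blocks = length // config.gap_block_size
        n_gaps = int(round(config.coverage_gap_fraction * n_blocks))
        if n_gaps:
            gaps = rng.choice(n_blocks, size=n_gaps, replace=False)
            for b in gaps:
                s = b * config.gap_block_size
                covered[s:s + config.gap_block_size] = False
        if config.coverage_gap_fraction >= 1.0:
            covered[:] = False
        if not covered.any():
            continue
        # run-length encode covered stretches of equal value
        change = np.empty(length, dtype=bool)
        change[0] = True
        change[1:] = (values[1:] != values[:-1]) | (covered[1:] != covered[:-1])
        starts = np.flatnonzero(change)
        ends = np.append(starts[1:], length)
        keep = covered[starts]
        data[chrom] = (starts[keep], ends[keep], values[starts[keep]])
    return SignalTrack(data)


# ---------------------------------------------------------------------------
# one-call dataset emission
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Generate every artifact and write it as plain text under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = simulate_genome(config)
    events = simulate_events(truth, config)
    gene_counts, exon_counts, truth = simulate_counts(
        config, exons=annotation, truth=truth)
    track = simulate_signal(annotation, truth, config)

    paths = {
        "genome": outdir / "genome.fa",
        "exons": outdir / "exons.bed",
        "comparisons": outdir / "comparisons.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "exon_counts": outdir / "exon_counts.tsv",
        "samples": outdir / "samples.tsv",
        "signal": outdir / "signal.bedgraph",
        "truth_exons": outdir / "truth_exons.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "config": outdir / "config.txt",
    }
    write_fasta(genome, paths["genome"])
    write_bed(annotation, paths["exons"])
    write_comparison_table(events, paths["comparisons"])
    write_counts(gene_counts, paths["gene_counts"])
    write_counts(exon_counts, paths["exon_counts"])
    truth.samples[["sample", "group", "replicate"]].to_csv(
        paths["samples"], sep="\t", index=False)
    write_bedgraph(track, paths["signal"])
    truth.exons.to_csv(paths["truth_exons"], sep="\t", index=False)
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    config.to_file(paths["config"])
    return paths
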