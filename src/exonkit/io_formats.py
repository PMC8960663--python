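"""Readers, writers and domain containers for the formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) on both strands;
strand only affects how sequence and signal are *oriented* when fetched,
never how intervals are stored.  Sequences are upper-case over {A,C,G,T,N};
any other IUPAC code is mapped to N on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

logger = logging.getLogger("exonkit")

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes (and anything else alphabetic) collapse to N
_TO_N = {c: "N" for c in "RYSWKMBDHVUryswkmbdhvu"}
_IUPAC_TABLE = str.maketrans(_TO_N)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Record-level constraint violation; message names the offending row."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based, stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Coordinate identity used for deduplication and set operations."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class ExonRecord:
    interval: GenomicInterval
    exon_id: str
    gene_id: str
    transcript_ids: frozenset = frozenset()


@dataclass(frozen=True)
class ComparisonRecord:
    """One differential-splicing call for one exon in one replicate."""

    event_id: str
    exon: GenomicInterval
    gene_id: str
    group: str
    replicate: int
    psi_control: float
    psi_treatment: float
    bayes_factor: float

    def __post_init__(self) -> None:
        for name in ("psi_control", "psi_treatment"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.bayes_factor < 0:
            raise ValidationError(f"bayes_factor={self.bayes_factor} negative")
        if self.replicate < 1:
            raise ValidationError(f"replicate={self.replicate} must be >= 1")

    @property
    def delta_psi(self) -> float:
        return self.psi_treatment - self.psi_control


class GenomeSequence:
    """In-memory genome: per-chromosome upper-case sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper().translate(_IUPAC_TABLE)
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ParseError(f"chromosome {chrom}: invalid symbols {sorted(bad)}")
            self._seqs[chrom] = seq

    @property
    def chromosomes(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]) or start > end:
            raise IndexError(
                f"[{start}, {end}) outside {chrom} bounds [0, {len(self._seqs[chrom])})"
            )
        return self._seqs[chrom][start:end]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_oriented(genome: GenomeSequence, interval: GenomicInterval) -> str:
    """Sequence of ``interval`` reading 5'->3' in transcription orientation."""
    seq = genome.fetch(interval.chrom, interval.start, interval.end)
    return reverse_complement(seq) if interval.strand == "-" else seq


class SignalTrack:
    """Sparse per-base signal: sorted non-overlapping intervals with values.

    Positions not covered by any interval are *missing* and are surfaced as
    NaN by :meth:`per_base`; how missing is treated (dropped vs zero-filled)
    is each consumer's decision.
    """

    def __init__(self, intervals: Mapping[str, tuple] | None = None):
        # per chrom: (starts, ends, values) as float/int arrays, sorted by start
        self._data: Dict[str, tuple] = {}
        if intervals:
            for chrom, (starts, ends, values) in intervals.items():
                self._set_chrom(chrom, np.asarray(starts, dtype=np.int64),
                                np.asarray(ends, dtype=np.int64),
                                np.asarray(values, dtype=float))

    def _set_chrom(self, chrom, starts, ends, values) -> None:
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise ParseError(f"{chrom}: empty or inverted interval")
        if np.any(starts[1:] < ends[:-1]):
            raise ParseError(f"{chrom}: overlapping intervals")
        if not np.all(np.isfinite(values)):
            raise ParseError(f"{chrom}: non-finite signal value")
        self._data[chrom] = (starts, ends, values)

    @property
    def chromosomes(self) -> List[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> tuple:
        return self._data[chrom]

    def covered_bases(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self._data.values()))

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); NaN where missing.

        Coordinates may extend past the covered range (or below zero):
        those positions are simply missing.
        """
        n = end - start
        out = np.full(n, np.nan)
        if chrom not in self._data or n <= 0:
            return out
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if a < b:
                out[a:b] = values[i]
        return out


class CountMatrix:
    """Non-negative integer counts, rows = genes or exons, columns = samples."""

    def __init__(self, counts: pd.DataFrame, groups: Optional[Mapping[str, str]] = None):
        if counts.index.duplicated().any():
            raise ValidationError("duplicate row ids in count matrix")
        if counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValidationError("non-integer count")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative count")
        self.counts = counts.astype(np.int64)
        self.groups = dict(groups) if groups else {}

    @property
    def row_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file; sequences are upper-cased and IUPAC codes become N.

    Duplicate headers and sequence lines outside a record are parse errors
    that name the offending line number.
    """
    seqs: Dict[str, List[str]] = {}
    current: Optional[str] = None
    mapped_n = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                if name in seqs:
                    raise ParseError(f"{path}: duplicate header {name!r} at line {lineno}")
                seqs[name] = []
                current = name
            else:
                if current is None:
                    raise ParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunk = line.strip().upper()
                if any(c not in "ACGTN" and not c.isalpha() for c in chunk):
                    raise ParseError(f"{path}: non-sequence characters at line {lineno}")
                mapped = chunk.translate(_IUPAC_TABLE)
                if mapped != chunk:
                    mapped_n = True
                seqs[current].append(mapped)
    if mapped_n:
        logger.warning("%s: ambiguous IUPAC bases mapped to N", path)
    return GenomeSequence({name: "".join(parts) for name, parts in seqs.items()})


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, genome.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def _parse_bed_name(name: str):
    """``gene|exon|t1,t2`` -> (gene_id, exon_id, transcripts); else exon_id only."""
    parts = name.split("|")
    if len(parts) == 3:
        gene_id, exon_id, txt = parts
        transcripts = frozenset(t for t in txt.split(",") if t)
        return gene_id, exon_id, transcripts
    return "", name, frozenset()


def read_bed(path) -> List[ExonRecord]:
    records: List[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: expected 6 BED columns at line {lineno}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            try:
                interval = GenomicInterval(chrom, start_i, end_i, strand)
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            gene_id, exon_id, transcripts = _parse_bed_name(name)
            records.append(ExonRecord(interval, exon_id, gene_id, transcripts))
    return records


def write_bed(records: Iterable[ExonRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            if rec.gene_id or rec.transcript_ids:
                name = "|".join(
                    [rec.gene_id, rec.exon_id, ",".join(sorted(rec.transcript_ids))]
                )
            else:
                name = rec.exon_id
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> SignalTrack:
    per_chrom: Dict[str, List[tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: expected 4 columns at line {lineno}")
            chrom, start, end, value = fields
            try:
                start_i, end_i, val = int(start), int(end), float(value)
            except ValueError as exc:
                raise ParseError(f"{path}: bad numeric field at line {lineno}") from exc
            per_chrom.setdefault(chrom, []).append((start_i, end_i, val))
    data = {}
    for chrom, rows in per_chrom.items():
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        data[chrom] = (starts, ends, values)
    return SignalTrack(data)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# comparison tables (normalized MISO-like TSV)
# ---------------------------------------------------------------------------

_COMPARISON_COLUMNS = [
    "event_id", "chrom", "start", "end", "strand", "gene_id",
    "group", "replicate", "psi_control", "psi_treatment", "bayes_factor",
]


def read_comparison_table(path) -> List[ComparisonRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COMPARISON_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records: List[ComparisonRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            interval = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
            rec = ComparisonRecord(
                event_id=row.event_id,
                exon=interval,
                gene_id=row.gene_id,
                group=row.group,
                replicate=int(row.replicate),
                psi_control=float(row.psi_control),
                psi_treatment=float(row.psi_treatment),
                bayes_factor=float(row.bayes_factor),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    return records


def comparison_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    rows = [
        {
            "event_id": r.event_id,
            "chrom": r.exon.chrom,
            "start": r.exon.start,
            "end": r.exon.end,
            "strand": r.exon.strand,
            "gene_id": r.gene_id,
            "group": r.group,
            "replicate": r.replicate,
            "psi_control": r.psi_control,
            "psi_treatment": r.psi_treatment,
            "bayes_factor": r.bayes_factor,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COMPARISON_COLUMNS)


def write_comparison_table(records: Sequence[ComparisonRecord], path) -> None:
    comparison_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices and sample sheets
# ---------------------------------------------------------------------------

def read_counts(path, sample_sheet=None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated row ids {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric counts")
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative count")
    if not np.allclose(values, np.round(values), atol=0):
        raise ValidationError(f"{path}: non-integer count")
    groups = None
    if sample_sheet is not None:
        sheet = read_sample_sheet(sample_sheet)
        groups = dict(zip(sheet["sample"], sheet["group"]))
    return CountMatrix(df.astype(np.int64), groups=groups)


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ParseError(f"{path}: sample sheet missing column {col!r}")
    return sheet
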