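"""Differential-splicing event filtering and classification.

The filter chain applied per comparison group is:

1. Bayes-factor evidence (strictly greater than the threshold, default 10).
2. Replicate reconciliation: any sign conflict in delta-PSI across an
   exon's records discards the exon; otherwise it is retained when at least
   one record passes the Bayes threshold (``require_all_reps`` tightens this
   to every record).
3. Redundant-form removal: among exons sharing a 5' or 3' boundary (in
   transcription orientation) the longest form defines the event; forms
   shorter than half of it are dropped.
4. Deduplication: exact coordinate duplicates collapse to one call;
   duplicates with conflicting directions are dropped.
5. Cross-group discard: an exon called in two groups with opposite
   directions is removed from both.

Directions are ``included`` (delta-PSI > 0) or ``skipped`` (< 0); exactly
zero delta-PSI is ambiguous and discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .io_formats import ComparisonRecord, CountMatrix, ExonRecord, GenomicInterval

logger = logging.getLogger("exonkit")

BAYES_THRESHOLD = 10.0
INCLUDED = "included"
SKIPPED = "skipped"


@dataclass
class ExonCall:
    """Per-exon consensus after replicate reconciliation."""

    exon: GenomicInterval
    gene_id: str
    group: str
    direction: str
    consensus_delta_psi: float
    n_replicates: int
    provenance: tuple = ()


@dataclass
class FilteredEventSet:
    group: str
    calls: Dict[tuple, ExonCall] = field(default_factory=dict)
    discards: List[dict] = field(default_factory=list)

    @property
    def exon_keys(self) -> Set[tuple]:
        return set(self.calls)

    def directions(self) -> Dict[tuple, str]:
        return {k: c.direction for k, c in self.calls.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c.exon.chrom, "start": c.exon.start, "end": c.exon.end,
                "strand": c.exon.strand, "gene_id": c.gene_id, "group": c.group,
                "direction": c.direction,
                "consensus_delta_psi": c.consensus_delta_psi,
                "n_replicates": c.n_replicates,
            }
            for c in self.calls.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "strand", "gene_id", "group",
                     "direction", "consensus_delta_psi", "n_replicates"],
        ).sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)


def filter_bayes(records: Sequence[ComparisonRecord],
                 threshold: float = BAYES_THRESHOLD) -> List[ComparisonRecord]:
    """Keep records with Bayes factor strictly greater than ``threshold``."""
    return [r for r in records if r.bayes_factor > threshold]


def reconcile_replicates(records: Sequence[ComparisonRecord],
                         threshold: float = BAYES_THRESHOLD,
                         require_all_reps: bool = False) -> FilteredEventSet:
    """Collapse a single group's records to per-exon consensus calls.

    Sees *unfiltered* records: the sign-conflict discard considers every
    replicate record for the exon, whatever its evidence, while retention
    requires Bayes support as described in the module docstring.
    """
    groups = {r.group for r in records}
    if len(groups) > 1:
        raise ValueError(f"records span multiple groups: {sorted(groups)}")
    group = groups.pop() if groups else ""
    out = FilteredEventSet(group=group)
    by_exon: Dict[tuple, List[ComparisonRecord]] = {}
    for r in records:
        by_exon.setdefault(r.exon.key, []).append(r)
    for key, recs in by_exon.items():
        deltas = [r.delta_psi for r in recs]
        if any(d == 0.0 for d in deltas):
            out.discards.append({"exon": key, "group": group,
                                 "reason": "ambiguous-direction"})
            logger.info("discard %s (%s): zero delta-PSI", key, group)
            continue
        if any(a * b < 0 for a in deltas for b in deltas):
            out.discards.append({"exon": key, "group": group,
                                 "reason": "opposite-effects"})
            continue
        passing = [r for r in recs if r.bayes_factor > threshold]
        ok = len(passing) == len(recs) if require_all_reps else len(passing) >= 1
        if not ok:
            out.discards.append({"exon": key, "group": group,
                                 "reason": "bayes-factor"})
            continue
        direction = INCLUDED if deltas[0] > 0 else SKIPPED
        out.calls[key] = ExonCall(
            exon=recs[0].exon,
            gene_id=recs[0].gene_id,
            group=group,
            direction=direction,
            consensus_delta_psi=sum(deltas) / len(deltas),
            n_replicates=len({r.replicate for r in recs}),
            provenance=tuple(recs),
        )
    return out


def _five_prime_boundary(iv: GenomicInterval) -> tuple:
    """Transcription-orientation 5' boundary identity (start on +, end on -)."""
    pos = iv.start if iv.strand == "+" else iv.end
    return (iv.chrom, iv.strand, "5", pos)


def _three_prime_boundary(iv: GenomicInterval) -> tuple:
    pos = iv.end if iv.strand == "+" else iv.start
    return (iv.chrom, iv.strand, "3", pos)


def remove_redundant_forms(event_set: FilteredEventSet,
                           min_fraction: float = 0.5) -> FilteredEventSet:
    """Drop short redundant exon forms that share a splice-site boundary.

    Exons sharing chrom+strand and an identical 5' or 3' boundary are
    alternate forms of one event; any form shorter than ``min_fraction``
    of the longest in its boundary group is discarded.
    """
    groups: Dict[tuple, List[tuple]] = {}
    for key, call in event_set.calls.items():
        for boundary in (_five_prime_boundary(call.exon),
                         _three_prime_boundary(call.exon)):
            groups.setdefault(boundary, []).append(key)
    doomed: Set[tuple] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        longest = max(event_set.calls[k].exon.length for k in members)
        for k in members:
            if event_set.calls[k].exon.length < min_fraction * longest:
                doomed.add(k)
    out = FilteredEventSet(group=event_set.group, discards=list(event_set.discards))
    for key, call in event_set.calls.items():
        if key in doomed:
            out.discards.append({"exon": key, "group": event_set.group,
                                 "reason": "redundant-form"})
        else:
            out.calls[key] = call
    return out


def deduplicate(calls: Iterable[ExonCall], group: str = "") -> FilteredEventSet:
    """Collapse exact coordinate duplicates; direction conflicts are dropped."""
    out = FilteredEventSet(group=group)
    conflicted: Set[tuple] = set()
    for call in calls:
        key = call.exon.key
        if key in conflicted:
            continue
        prior = out.calls.get(key)
        if prior is None:
            out.calls[key] = call
        elif prior.direction != call.direction:
            del out.calls[key]
            conflicted.add(key)
            out.discards.append({"exon": key, "group": group,
                                 "reason": "direction-conflict"})
    return out


def cross_group_discard(sets: Mapping[str, FilteredEventSet]) -> Dict[str, FilteredEventSet]:
    """Remove exons called with opposite directions in two different groups."""
    direction_sets: Dict[tuple, Set[str]] = {}
    for s in sets.values():
        for key, call in s.calls.items():
            direction_sets.setdefault(key, set()).add(call.direction)
    doomed = {key for key, dirs in direction_sets.items() if len(dirs) > 1}
    out: Dict[str, FilteredEventSet] = {}
    for group, s in sets.items():
        pruned = FilteredEventSet(group=group, discards=list(s.discards))
        for key, call in s.calls.items():
            if key in doomed:
                pruned.discards.append({"exon": key, "group": group,
                                        "reason": "cross-group-conflict"})
            else:
                pruned.calls[key] = call
        out[group] = pruned
    return out


def filter_events(records: Sequence[ComparisonRecord],
                  threshold: float = BAYES_THRESHOLD,
                  require_all_reps: bool = False) -> Dict[str, FilteredEventSet]:
    """Run the full per-group filter chain plus the cross-group discard."""
    by_group: Dict[str, List[ComparisonRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    sets: Dict[str, FilteredEventSet] = {}
    for group, recs in sorted(by_group.items()):
        reconciled = reconcile_replicates(recs, threshold=threshold,
                                          require_all_reps=require_all_reps)
        pruned = remove_redundant_forms(reconciled)
        deduped = deduplicate(pruned.calls.values(), group=group)
        deduped.discards = pruned.discards + deduped.discards
        sets[group] = deduped
    return cross_group_discard(sets)


def intersect_groups(sets: Mapping[str, FilteredEventSet]) -> pd.DataFrame:
    """Venn/upset region counts over exon coordinate keys.

    One row per non-empty membership pattern; ``groups`` is a '+'-joined
    sorted label and ``count`` the number of exons exclusive to that region.
    """
    names = sorted(sets)
    membership: Dict[tuple, Tuple[str, ...]] = {}
    for name in names:
        for key in sets[name].exon_keys:
            membership[key] = membership.get(key, ()) + (name,)
    counts: Dict[Tuple[str, ...], int] = {}
    for pattern in membership.values():
        counts[pattern] = counts.get(pattern, 0) + 1
    rows = [
        {"groups": "+".join(pattern), "n_groups": len(pattern), "count": n}
        for pattern, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["groups", "n_groups", "count"])


def expressed_exons(exon_counts: CountMatrix,
                    control_samples: Sequence[str]) -> Set[str]:
    """Exons with a nonzero count in *every* named control sample."""
    missing = [s for s in control_samples if s not in exon_counts.samples]
    if missing:
        raise KeyError(f"control samples absent from count matrix: {missing}")
    sub = exon_counts.counts[list(control_samples)]
    mask = (sub > 0).all(axis=1)
    return set(sub.index[mask])


# ---------------------------------------------------------------------------
# event classification (UCSC-style)
# ---------------------------------------------------------------------------

CASSETTE = "cassette"
BLEEDING = "bleeding_exon"
RETAINED_INTRON = "retained_intron"
OTHER = "other"


def build_transcript_models(annotation: Sequence[ExonRecord]) -> Dict[str, Dict[str, List[GenomicInterval]]]:
    """gene_id -> transcript_id -> exons ordered by genomic start."""
    models: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    for rec in annotation:
        for tx in rec.transcript_ids or {rec.exon_id}:
            models.setdefault(rec.gene_id, {}).setdefault(tx, []).append(rec.interval)
    for transcripts in models.values():
        for tx in transcripts:
            transcripts[tx] = sorted(set(transcripts[tx]), key=lambda iv: (iv.start, iv.end))
    return models


def classify_event(exon: GenomicInterval, gene_id: str,
                   models: Mapping[str, Mapping[str, List[GenomicInterval]]]) -> str:
    """Classify one exon against its gene's transcript structures.

    cassette: internal in one transcript, absent from another transcript of
    the gene in which both flanking exons appear with identical boundaries.
    retained_intron: spans two adjacent exons of another transcript plus the
    intervening intron exactly.  bleeding_exon: shares exactly one boundary
    with an annotated exon and runs past the other into the intron.
    """
    if gene_id not in models:
        raise KeyError(f"gene {gene_id!r} absent from annotation")
    transcripts = models[gene_id]
    coords = (exon.chrom, exon.start, exon.end)

    def same_coords(iv: GenomicInterval) -> bool:
        return (iv.chrom, iv.start, iv.end) == coords

    # cassette
    for tx, exons in transcripts.items():
        idx = next((i for i, iv in enumerate(exons) if same_coords(iv)), None)
        if idx is None or idx == 0 or idx == len(exons) - 1:
            continue
        left, right = exons[idx - 1], exons[idx + 1]
        for other_tx, other_exons in transcripts.items():
            if other_tx == tx:
                continue
            keys = {(iv.start, iv.end) for iv in other_exons}
            if ((left.start, left.end) in keys and (right.start, right.end) in keys
                    and (exon.start, exon.end) not in keys):
                return CASSETTE
    # retained intron
    for exons in transcripts.values():
        for a, b in zip(exons, exons[1:]):
            if exon.start == a.start and exon.end == b.end and a.end < b.start:
                return RETAINED_INTRON
    # bleeding exon
    for exons in transcripts.values():
        for iv in exons:
            if same_coords(iv):
                continue
            share_start = exon.start == iv.start and exon.end != iv.end
            share_end = exon.end == iv.end and exon.start != iv.start
            if share_start and exon.end > iv.end:
                return BLEEDING
            if share_end and exon.start < iv.start:
                return BLEEDING
    return OTHER


def classify_events(exons: Sequence[ExonRecord],
                    annotation: Sequence[ExonRecord]) -> pd.DataFrame:
    models = build_transcript_models(annotation)
    rows = []
    for rec in exons:
        cls = classify_event(rec.interval, rec.gene_id, models)
        rows.append({
            "chrom": rec.interval.chrom, "start": rec.interval.start,
            "end": rec.interval.end, "strand": rec.interval.strand,
            "gene_id": rec.gene_id, "exon_id": rec.exon_id, "event_class": cls,
        })
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id", "exon_id",
                       "event_class"])
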