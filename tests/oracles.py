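"""Independent brute-force reference implementations used only for testing.

Everything here materializes the rules literally (per-base loops, pairwise
comparisons, explicit OLS sums) and deliberately shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# event filtering: literal rule-by-rule survivor computation
# ---------------------------------------------------------------------------

def brute_force_survivors(records, threshold: float = 10.0,
                          require_all_reps: bool = False) -> Dict[str, Dict[tuple, str]]:
    """{group: {exon_key: direction}} applying every filtering rule literally."""
    by_group: Dict[str, list] = defaultdict(list)
    for r in records:
        by_group[r.group].append(r)
    per_group: Dict[str, Dict[tuple, str]] = {}
    for group, recs in by_group.items():
        by_exon: Dict[tuple, list] = defaultdict(list)
        for r in recs:
            key = (r.exon.chrom, r.exon.start, r.exon.end, r.exon.strand)
            by_exon[key].append(r)
        calls: Dict[tuple, str] = {}
        for key, rs in by_exon.items():
            deltas = [r.psi_treatment - r.psi_control for r in rs]
            if any(d == 0.0 for d in deltas):
                continue
            if any(d > 0 for d in deltas) and any(d < 0 for d in deltas):
                continue
            n_passing = sum(1 for r in rs if r.bayes_factor > threshold)
            if require_all_reps:
                if n_passing != len(rs):
                    continue
            elif n_passing < 1:
                continue
            calls[key] = "included" if deltas[0] > 0 else "skipped"
        # redundant forms: pairwise, shared start or shared end, same chrom+strand
        doomed = set()
        keys = list(calls)
        for a in keys:
            for b in keys:
                if a == b or a[0] != b[0] or a[3] != b[3]:
                    continue
                shares = a[1] == b[1] or a[2] == b[2]
                if shares and (a[2] - a[1]) < 0.5 * (b[2] - b[1]):
                    doomed.add(a)
        per_group[group] = {k: v for k, v in calls.items() if k not in doomed}
    # cross-group: opposite directions in two groups remove the exon everywhere
    direction_sets: Dict[tuple, set] = defaultdict(set)
    for calls in per_group.values():
        for key, direction in calls.items():
            direction_sets[key].add(direction)
    conflicted = {k for k, dirs in direction_sets.items() if len(dirs) > 1}
    return {group: {k: v for k, v in calls.items() if k not in conflicted}
            for group, calls in per_group.items()}


def brute_force_regions(sets: Dict[str, set]) -> Dict[Tuple[str, ...], int]:
    """Venn region counts by enumerating membership of every element."""
    universe = set().union(*sets.values()) if sets else set()
    regions: Dict[Tuple[str, ...], int] = defaultdict(int)
    for element in universe:
        pattern = tuple(sorted(name for name, s in sets.items() if element in s))
        regions[pattern] += 1
    return dict(regions)


# ---------------------------------------------------------------------------
# GC binning: per-base fractional weights, no shortcuts
# ---------------------------------------------------------------------------

def brute_force_gc_bins(sequence: str, n_bins: int) -> List[float]:
    L = len(sequence)
    out = []
    for i in range(n_bins):
        a = i * L / n_bins
        b = (i + 1) * L / n_bins
        num = den = 0.0
        for j, ch in enumerate(sequence):
            w = min(j + 1, b) - max(j, a)
            if w > 0 and ch != "N":
                den += w
                num += w * (1.0 if ch in "GC" else 0.0)
        out.append(num / den if den > 0 else float("nan"))
    return out


# ---------------------------------------------------------------------------
# signal scale-regions: materialize every base, zero-fill, average
# ---------------------------------------------------------------------------

def brute_force_per_base(track, chrom: str, start: int, end: int) -> List[float]:
    """Per-base values with missing -> 0, walking the track interval list."""
    out = []
    for pos in range(start, end):
        value = 0.0
        if chrom in track.chromosomes:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                if s <= pos < e:
                    value = float(v)
                    break
        out.append(value)
    return out


def brute_force_rebin(values: Sequence[float], n_bins: int) -> List[float]:
    L = len(values)
    out = []
    for i in range(n_bins):
        a = i * L / n_bins
        b = (i + 1) * L / n_bins
        num = den = 0.0
        for j, v in enumerate(values):
            w = min(j + 1, b) - max(j, a)
            if w > 0:
                den += w
                num += w * v
        out.append(num / den)
    return out


def brute_force_scale_region(track, exon, flank: int = 500,
                             body_length: int = 100,
                             bin_size: int = 20) -> List[float]:
    chrom = exon.chrom
    up = brute_force_per_base(track, chrom, exon.start - flank, exon.start)
    body = brute_force_per_base(track, chrom, exon.start, exon.end)
    down = brute_force_per_base(track, chrom, exon.end, exon.end + flank)
    if exon.strand == "-":
        up, down = down[::-1], up[::-1]
        body = body[::-1]
    scaled = brute_force_rebin(body, body_length)
    vec = (brute_force_rebin(up, flank // bin_size)
           + brute_force_rebin(scaled, body_length // bin_size)
           + brute_force_rebin(down, flank // bin_size))
    return vec


# ---------------------------------------------------------------------------
# splice sites: direct string slicing
# ---------------------------------------------------------------------------

def brute_force_site_tris(genome_seq: str, start: int, end: int, strand: str,
                          convention: str = "exonic"):
    """(acceptor, donor) trinucleotide by explicit slicing of one chromosome."""
    if convention == "exonic":
        body = genome_seq[start:end]
        if strand == "-":
            body = revcomp(body)
        three, five = body[:3], body[-3:]
    else:
        if strand == "+":
            three = genome_seq[start - 3:start] if start >= 3 else None
            five = genome_seq[end:end + 3] if end + 3 <= len(genome_seq) else None
        else:
            three = genome_seq[end:end + 3] if end + 3 <= len(genome_seq) else None
            five = genome_seq[start - 3:start] if start >= 3 else None
            three = revcomp(three) if three else None
            five = revcomp(five) if five else None
    if three is not None and ("N" in three or len(three) < 3):
        three = None
    if five is not None and ("N" in five or len(five) < 3):
        five = None
    return three, five


# ---------------------------------------------------------------------------
# HVG selection: explicit OLS sums
# ---------------------------------------------------------------------------

def brute_force_hvg(means: Sequence[float], cv2s: Sequence[float],
                    gene_ids: Sequence[str], n_top: int) -> List[str]:
    rows = [(g, m, c) for g, m, c in zip(gene_ids, means, cv2s)
            if m > 0 and c > 0 and not math.isnan(c)]
    xs = [math.log(m) for _, m, _ in rows]
    ys = [math.log(c) for _, _, c in rows]
    n = len(rows)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    scored = [(y - (slope * x + intercept), c, g)
              for (g, _, c), x, y in zip(rows, xs, ys)]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [g for _, _, g in scored[:n_top]]
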