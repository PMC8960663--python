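"""Length-normalized GC-content metaprofiles over exon sets.

Each exon contributes a vector of 500 upstream flank positions at native
scale, 100 exon-body bins (each covering 1% of the exon length, with
fractional base weights for lengths not divisible by 100), and 500
downstream flank positions, all read 5'->3' in transcription orientation.
Profiles are averaged per position across exons, smoothed with a trailing
moving average, and compared against a scalar background: the unweighted
mean whole-body GC fraction of an expressed-exon set.

N bases (and flank positions clipped at chromosome ends) are missing and
are excluded from both numerator and denominator of every mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExonRecord, GenomeSequence, GenomicInterval, fetch_oriented

DEFAULT_FLANK = 500
DEFAULT_BINS = 100
DEFAULT_SMOOTH = 10

_GC_BYTES = (ord("G"), ord("C"))


@dataclass
class MetaProfile:
    """Position-indexed aggregate: mean, optional stderr, per-position n."""

    mean: np.ndarray
    n: np.ndarray
    stderr: Optional[np.ndarray] = None
    background: Optional[float] = None
    flank: int = DEFAULT_FLANK
    n_body_bins: int = DEFAULT_BINS

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.n = np.asarray(self.n)

    def __len__(self) -> int:
        return len(self.mean)

    @property
    def regions(self) -> np.ndarray:
        labels = (["upstream"] * self.flank
                  + ["body"] * self.n_body_bins
                  + ["downstream"] * self.flank)
        return np.array(labels)

    def body_slice(self) -> slice:
        return slice(self.flank, self.flank + self.n_body_bins)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "position_index": np.arange(1, len(self.mean) + 1),
            "region": self.regions,
            "mean": self.mean,
            "n": self.n,
        })
        if self.stderr is not None:
            df["stderr"] = self.stderr
        if self.background is not None:
            df["background"] = self.background
        return df


def gc_indicator(sequence: str) -> np.ndarray:
    """Per-base G/C indicator (1.0/0.0) with NaN for N."""
    b = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.isin(b, _GC_BYTES).astype(float)
    out[b == ord("N")] = np.nan
    return out


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); NaN if no unambiguous base is present."""
    if not sequence:
        return float("nan")
    ind = gc_indicator(sequence)
    if np.all(np.isnan(ind)):
        return float("nan")
    return float(np.nanmean(ind))


def rebin_fractional(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rebin per-base values into ``n_bins`` equal windows of length L/n_bins.

    Bases straddling a window edge contribute with fractional weight equal
    to their overlap.  NaN entries carry zero weight; a window whose total
    weight is zero yields NaN.  Exact for any L (integral of the step
    function via linear interpolation of its cumulative sum).
    """
    values = np.asarray(values, dtype=float)
    L = len(values)
    if L == 0:
        raise ValueError("cannot rebin an empty vector")
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    mask = ~np.isnan(values)
    v = np.where(mask, values, 0.0)
    grid = np.arange(L + 1, dtype=float)
    cum_v = np.concatenate(([0.0], np.cumsum(v)))
    cum_w = np.concatenate(([0.0], np.cumsum(mask.astype(float))))
    edges = np.linspace(0.0, float(L), n_bins + 1)
    num = np.diff(np.interp(edges, grid, cum_v))
    den = np.diff(np.interp(edges, grid, cum_w))
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def exon_gc_bins(sequence: str, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """GC fraction in ``n_bins`` windows each covering 1/n_bins of the exon."""
    if len(sequence) == 0:
        raise ValueError("empty exon sequence")
    return rebin_fractional(gc_indicator(sequence), n_bins)


def flank_positions(exon: GenomicInterval, genome: GenomeSequence,
                    flank: int = DEFAULT_FLANK) -> tuple:
    """Per-base GC indicators for the upstream and downstream flanks.

    Orientation follows transcription: on '-' the upstream flank lies
    genomically after the exon and both vectors are read towards/away from
    the exon in 5'->3' order.  Positions beyond chromosome ends are NaN
    (padded on the far side of each flank).
    """
    chrom_len = genome.length(exon.chrom)

    def fetch_clipped(start: int, end: int) -> np.ndarray:
        lo, hi = max(start, 0), min(end, chrom_len)
        vec = np.full(end - start, np.nan)
        if lo < hi:
            vec[lo - start:hi - start] = gc_indicator(
                genome.fetch(exon.chrom, lo, hi))
        return vec

    left = fetch_clipped(exon.start - flank, exon.start)
    right = fetch_clipped(exon.end, exon.end + flank)
    if exon.strand == "+":
        return left, right
    return right[::-1], left[::-1]


def exon_profile_vector(exon: GenomicInterval, genome: GenomeSequence,
                        flank: int = DEFAULT_FLANK,
                        n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """upstream flank + length-normalized body + downstream flank, oriented."""
    up, down = flank_positions(exon, genome, flank=flank)
    body = exon_gc_bins(fetch_oriented(genome, exon), n_bins=n_bins)
    return np.concatenate([up, body, down])


def aggregate_gc_profile(exons: Sequence[ExonRecord | GenomicInterval],
                         genome: GenomeSequence,
                         flank: int = DEFAULT_FLANK,
                         n_bins: int = DEFAULT_BINS) -> MetaProfile:
    """Per-position mean GC across an exon set, ignoring missing entries."""
    intervals = [e.interval if isinstance(e, ExonRecord) else e for e in exons]
    if not intervals:
        raise ValueError("empty exon set")
    matrix = np.vstack([
        exon_profile_vector(iv, genome, flank=flank, n_bins=n_bins)
        for iv in intervals
    ])
    n = np.sum(~np.isnan(matrix), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(matrix, axis=0) / np.maximum(n, 1), np.nan)
    return MetaProfile(mean=mean, n=n, flank=flank, n_body_bins=n_bins)


def smooth_profile(profile: MetaProfile, window: int = DEFAULT_SMOOTH) -> MetaProfile:
    """Trailing moving average; shorter windows at the left edge."""
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = (pd.Series(profile.mean)
                .rolling(window=window, min_periods=1).mean()
                .to_numpy())
    return MetaProfile(mean=smoothed, n=profile.n.copy(),
                       background=profile.background,
                       flank=profile.flank, n_body_bins=profile.n_body_bins)


def background_gc(expressed_exons: Sequence[ExonRecord | GenomicInterval],
                  genome: GenomeSequence) -> float:
    """Mean whole-body GC over expressed exons, unweighted by exon length."""
    intervals = [e.interval if isinstance(e, ExonRecord) else e
                 for e in expressed_exons]
    if not intervals:
        raise ValueError("empty expressed-exon set")
    values = [gc_fraction(fetch_oriented(genome, iv)) for iv in intervals]
    return float(np.nanmean(values))
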