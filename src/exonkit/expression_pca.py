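"""Median-of-ratios normalization, CV^2-based variable-gene selection, PCA.

The procedure: (1) per-sample size factors as the median across genes of
the ratio of each gene's count to its geometric mean over samples,
restricted to genes positive in every sample; (2) counts divided by the
size factors; (3) genes with mean normalized expression below a floor
(default 2) removed; (4) ordinary least squares of log CV^2 on log mean;
(5) the genes with the largest positive residuals (default 100) selected;
(6) PCA of log(normalized + 1) over the selected genes, samples as
observations, gene-centered but not scaled, with the fraction of variance
per component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_formats import CountMatrix


@dataclass
class SizeFactors:
    factors: pd.Series      # per sample, > 0
    genes_used: int

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


@dataclass
class HVGSelection:
    stats: pd.DataFrame     # gene, mean, cv2, residual, selected
    slope: float
    intercept: float
    selected: List[str]


@dataclass
class PCAResult:
    scores: pd.DataFrame               # samples x components
    loadings: pd.DataFrame             # genes x components
    variance_explained: np.ndarray     # fractions, sum to 1


def size_factors(counts: CountMatrix | pd.DataFrame) -> SizeFactors:
    """DESeq-style median-of-ratios size factors.

    Only genes with strictly positive counts in every sample enter the
    per-sample median (the geometric mean is degenerate otherwise); the
    median is taken in log space, as DESeq2 does.  Size factors only fix
    *relative* library sizes, so the returned factors are rescaled to
    geometric mean 1 — the unique gauge in which renormalization is exactly
    idempotent (re-estimating factors on normalized counts yields 1).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    values = df.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    log_sub = np.log(values[positive])
    log_ratios = log_sub - log_sub.mean(axis=1, keepdims=True)
    log_factors = np.median(log_ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    factors = pd.Series(np.exp(log_factors), index=df.columns,
                        name="size_factor")
    return SizeFactors(factors=factors, genes_used=int(positive.sum()))


def normalize(counts: CountMatrix | pd.DataFrame,
              factors: SizeFactors) -> pd.DataFrame:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    return df / factors.factors


def filter_low(normalized: pd.DataFrame, min_reads: float = 2.0) -> pd.DataFrame:
    """Keep genes whose mean normalized count across samples is >= min_reads."""
    kept = normalized[normalized.mean(axis=1) >= min_reads]
    if kept.empty:
        raise ValueError("no genes pass the low-expression filter")
    return kept


def mean_cv2(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean and squared coefficient of variation (unbiased variance)."""
    if normalized.shape[1] < 2:
        raise ValueError("need at least two samples")
    mean = normalized.mean(axis=1)
    var = normalized.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, var / mean**2, np.nan)
    return pd.DataFrame({"mean": mean, "cv2": cv2})


def hvg_select(stats: pd.DataFrame, n_top: int = 100) -> HVGSelection:
    """Select the genes with the largest residual above the log-log fit.

    OLS of log(cv2) on log(mean) over genes with defined, positive cv2;
    residual = observed - fitted.  Ties break by larger cv2, then gene id.
    """
    usable = stats.dropna(subset=["cv2"])
    usable = usable[(usable["mean"] > 0) & (usable["cv2"] > 0)]
    if usable.empty:
        raise ValueError("no genes with defined positive CV^2")
    x = np.log(usable["mean"].to_numpy())
    y = np.log(usable["cv2"].to_numpy())
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all gene means equal")
    slope, intercept = np.polyfit(x, y, 1)
    residual = y - (slope * x + intercept)
    table = usable.assign(residual=residual)
    # stable mergesort + pre-sorted index gives the lexicographic id tiebreak
    order = table.sort_index().sort_values(
        by=["residual", "cv2"], ascending=[False, False], kind="mergesort")
    selected = list(order.index[:min(n_top, len(order))])
    table["selected"] = table.index.isin(selected)
    return HVGSelection(stats=table, slope=float(slope),
                        intercept=float(intercept), selected=selected)


def run_pca(normalized: pd.DataFrame, selection: HVGSelection | Sequence[str],
            pseudocount: float = 1.0) -> PCAResult:
    """PCA of log(normalized + pseudocount) over the selected genes.

    Samples are the observations; genes are mean-centered, not scaled.
    variance_explained holds the fraction of total variance on each
    component and sums to 1 over all computed components.
    """
    genes = selection.selected if isinstance(selection, HVGSelection) else list(selection)
    if not genes:
        raise ValueError("empty gene selection")
    if normalized.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = np.log(normalized.loc[genes].to_numpy(dtype=float).T + pseudocount)
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    k = scores.shape[1]
    comp_names = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=normalized.columns, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=genes, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
    )


def pca_pipeline(counts: CountMatrix | pd.DataFrame, n_top: int = 100,
                 min_reads: float = 2.0) -> tuple:
    """Full chain: size factors -> normalize -> filter -> HVG -> PCA."""
    factors = size_factors(counts)
    normalized = normalize(counts, factors)
    kept = filter_low(normalized, min_reads=min_reads)
    selection = hvg_select(mean_cv2(kept), n_top=n_top)
    result = run_pca(kept, selection)
    return factors, normalized, selection, result
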