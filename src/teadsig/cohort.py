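"""Marker-anchored validation in a tumor cohort.

Tumors are split into marker-high / marker-low groups at mean +/- 1 SD of
a canonical target gene's expression (e.g. CTGF or CYR61 on the log2(1+TPM)
scale); signature genes are compared between groups, correlated with the
marker by Spearman rank correlation with a permutation null, binned by
correlation strength, and summarized in a marker-sorted pairwise similarity
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

logger = logging.getLogger("teadsig")

BIN_STRONG = 0.4
BIN_MODERATE = 0.3


@dataclass
class MarkerGrouping:
    marker: str
    groups: pd.Series  # sample -> {high, low, neither}
    mean: float
    sd: float
    k: float = 1.0

    @property
    def high(self) -> list[str]:
        return list(self.groups.index[self.groups == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.groups.index[self.groups == "low"])


@dataclass
class CorrelationReport:
    """Per-gene Spearman r vs a marker with permutation p and strength bin
    (strong: r >= 0.4; moderate: 0.3 <= r < 0.4; weak: r < 0.3)."""

    marker: str
    table: pd.DataFrame  # index gene; columns spearman_r, permutation_p, bin, flagged


@dataclass
class SimilarityMatrix:
    """Gene x gene Spearman correlations, rows/columns sorted by the
    correlation with the anchor marker, descending."""

    matrix: pd.DataFrame
    anchor: str


def correlation_bin(r: float) -> str:
    if np.isnan(r):
        return "weak"
    if r >= BIN_STRONG:
        return "strong"
    if r >= BIN_MODERATE:
        return "moderate"
    return "weak"


def assign_groups(matrix: ExpressionMatrix, marker: str, k: float = 1.0) -> MarkerGrouping:
    """High / low grouping at mean +/- k SD of marker expression, inclusive
    boundaries; everything in between is 'neither'."""
    if matrix.value_space != "log2p1":
        raise ValueError("assign_groups expects log2p1 values")
    if marker not in matrix.values.index:
        raise ValueError(f"marker {marker!r} not in matrix")
    vals = matrix.values.loc[marker]
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd == 0:
        raise ValueError(f"degenerate marker {marker!r}: zero variance")
    groups = pd.Series("neither", index=vals.index, dtype=object)
    groups[vals >= mean + k * sd] = "high"
    groups[vals <= mean - k * sd] = "low"
    return MarkerGrouping(marker, groups, mean, sd, k)


def group_compare(
    matrix: ExpressionMatrix, grouping: MarkerGrouping, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney test of marker-high vs marker-low
    samples, BH-adjusted across the tested genes."""
    high, low = grouping.high, grouping.low
    if len(high) < 3 or len(low) < 3:
        raise ValueError(f"groups too small: {len(high)} high / {len(low)} low")
    genes = list(genes) if genes is not None else matrix.gene_ids
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    hi = matrix.values.loc[genes, high].to_numpy()
    lo = matrix.values.loc[genes, low].to_numpy()
    pvals = np.empty(len(genes))
    for i in range(len(genes)):
        if np.ptp(hi[i]) == 0 and np.ptp(lo[i]) == 0 and hi[i][0] == lo[i][0]:
            pvals[i] = 1.0
            continue
        pvals[i] = stats.mannwhitneyu(hi[i], lo[i], alternative="two-sided").pvalue
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "median_high": np.median(hi, axis=1),
            "median_low": np.median(lo, axis=1),
            "p": pvals,
            "fdr": fdr,
        },
        index=pd.Index(genes, name="gene"),
    )


def spearman_vs_marker(
    matrix: ExpressionMatrix,
    marker: str,
    genes: list[str] | None = None,
    nperm: int = 1000,
    seed: int | None = None,
) -> CorrelationReport:
    """Spearman correlation of each gene with the marker, with a
    marker-permutation p-value ((b+1)/(nperm+1) smoothing) and strength
    bins. Constant genes are flagged: r undefined -> weak bin, p = 1."""
    if matrix.n_samples < 5:
        raise ValueError("need >= 5 samples")
    if marker not in matrix.values.index:
        raise ValueError(f"marker {marker!r} not in matrix")
    genes = list(genes) if genes is not None else [g for g in matrix.gene_ids if g != marker]
    rng = np.random.default_rng(seed)
    mvals = matrix.values.loc[marker].to_numpy()
    m_rank = stats.rankdata(mvals)
    x = matrix.values.loc[genes].to_numpy()
    g_ranks = np.apply_along_axis(stats.rankdata, 1, x)
    constant = np.ptp(x, axis=1) == 0

    def corr_with(marker_ranks: np.ndarray) -> np.ndarray:
        mc = marker_ranks - marker_ranks.mean()
        gc = g_ranks - g_ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((gc**2).sum(axis=1) * (mc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (gc @ mc) / denom

    r_obs = corr_with(m_rank)
    exceed = np.zeros(len(genes))
    for _ in range(nperm):
        r_perm = corr_with(rng.permutation(m_rank))
        exceed += np.abs(r_perm) >= np.abs(r_obs)
    pperm = (exceed + 1.0) / (nperm + 1.0)
    r_out = np.where(constant, np.nan, r_obs)
    pperm = np.where(constant, 1.0, pperm)
    bins = [correlation_bin(r) for r in r_out]
    if constant.any():
        logger.warning("spearman_vs_marker: %d constant genes flagged", int(constant.sum()))
    table = pd.DataFrame(
        {"spearman_r": r_out, "permutation_p": pperm, "bin": bins, "flagged": constant},
        index=pd.Index(genes, name="gene"),
    )
    return CorrelationReport(marker, table)


def similarity_matrix(
    matrix: ExpressionMatrix, genes: list[str], anchor_marker: str
) -> SimilarityMatrix:
    """All-pairs Spearman correlations over samples, sorted by correlation
    with the anchor marker (highest first)."""
    genes = list(genes)
    if anchor_marker not in genes:
        genes = [anchor_marker] + genes
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    x = matrix.values.loc[genes].to_numpy()
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=genes, columns=genes)
    order = frame[anchor_marker].sort_values(ascending=False, kind="stable").index
    frame = frame.loc[order, order]
    return SimilarityMatrix(frame, anchor_marker)


def strong_correlation_venn(
    report_a: CorrelationReport,
    report_b: CorrelationReport,
    threshold: float = BIN_STRONG,
) -> dict[str, int]:
    """Counts of genes strongly correlated (r >= threshold, inclusive) with
    marker A only, marker B only, or both."""
    genes_a = set(report_a.table.index)
    genes_b = set(report_b.table.index)
    if genes_a != genes_b:
        raise ValueError("correlation reports cover different gene universes")
    ra = report_a.table["spearman_r"]
    rb = report_b.table["spearman_r"]
    strong_a = set(ra.index[ra >= threshold])
    strong_b = set(rb.index[rb >= threshold])
    return {
        "only_a": len(strong_a - strong_b),
        "only_b": len(strong_b - strong_a),
        "both": len(strong_a & strong_b),
    }
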