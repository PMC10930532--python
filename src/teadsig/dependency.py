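"""CRISPR dependency binarization and ROC-based dependence prediction.

Chronos fitness scores are binarized at a fixed threshold (a line is
dependent on a gene when its score is <= -0.65); group labels combine
per-gene calls (YAP/TAZ = YAP1 or WWTR1; TEAD = any of TEAD1-4). GSVA
enrichment scores of a signature are then evaluated as a classifier of
those labels with ROC analysis: Mann-Whitney AUC with ties counted 1/2, a
DeLong-variance test against AUC = 0.5, and the Youden-optimal cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GeneSet, log2p1
from .enrichment import GsvaScores, gsva

logger = logging.getLogger("teadsig")

YAP_TAZ_GENES = ("YAP1", "WWTR1")
TEAD_GENES = ("TEAD1", "TEAD2", "TEAD3", "TEAD4")
REQUIRED_GENES = YAP_TAZ_GENES + TEAD_GENES

CHRONOS_THRESHOLD = -0.65


@dataclass
class DependencyTable:
    """Cell line x gene Chronos dependency scores plus per-line lineage."""

    scores: pd.DataFrame
    lineage: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate cell lines")
        if self.lineage is not None:
            missing = self.scores.index.difference(self.lineage.index)
            if len(missing):
                raise ValueError(f"lineage missing for: {list(missing)[:5]}")

    def filter_lineage(self, lineage: str) -> "DependencyTable":
        if self.lineage is None:
            raise ValueError("no lineage annotation")
        keep = self.lineage.index[self.lineage == lineage]
        return DependencyTable(self.scores.loc[self.scores.index.intersection(keep)],
                               self.lineage.loc[self.lineage == lineage])


@dataclass
class DependencyLabels:
    """Per-line boolean dependence calls; ``table`` has one column per gene
    plus the combined YAP/TAZ and TEAD columns."""

    table: pd.DataFrame
    threshold: float = CHRONOS_THRESHOLD

    @property
    def dependent_yap_taz(self) -> pd.Series:
        return self.table["dependent_yap_taz"]

    @property
    def dependent_tead(self) -> pd.Series:
        return self.table["dependent_tead"]


@dataclass
class RocResult:
    auc: float
    auc_p: float
    youden_j: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    curve: pd.DataFrame = field(repr=False, default=None)


def binarize_dependency(
    table: DependencyTable,
    threshold: float = CHRONOS_THRESHOLD,
    required: tuple[str, ...] = REQUIRED_GENES,
) -> DependencyLabels:
    """Dependent iff Chronos score <= threshold (the boundary counts as
    dependent). Lines missing a score for any required gene are excluded
    with a log message."""
    missing_cols = [g for g in required if g not in table.scores.columns]
    if missing_cols:
        raise ValueError(f"dependency table missing genes: {missing_cols}")
    scores = table.scores[list(required)]
    complete = scores.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("binarize_dependency: %d lines with missing scores excluded", n_dropped)
    scores = scores[complete]
    calls = scores <= threshold
    out = calls.copy()
    yt = [g for g in YAP_TAZ_GENES if g in calls.columns]
    td = [g for g in TEAD_GENES if g in calls.columns]
    out["dependent_yap_taz"] = calls[yt].any(axis=1)
    out["dependent_tead"] = calls[td].any(axis=1)
    return DependencyLabels(out, threshold)


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise concordance probability with ties counted 1/2,
    via the rank-sum identity."""
    pos = labels.sum()
    neg = len(labels) - pos
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - pos * (pos + 1) / 2.0) / (pos * neg))


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC estimate for a single classifier."""
    x = scores[labels]  # positives
    y = scores[~labels]
    m, n = len(x), len(y)
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> RocResult:
    """ROC analysis of a real-valued score against boolean labels.

    The classifier calls positive when score >= cutoff; candidate cutoffs
    are midpoints between adjacent distinct scores (plus one beyond each
    extreme), the Youden-optimal cutoff maximizes sensitivity +
    specificity - 1, and J ties resolve to the lower cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")

    auc = _auc_mann_whitney(s, y)
    var = _delong_variance(s, y, auc)
    if var <= 0:
        p = 1.0 if np.isclose(auc, 0.5) else 0.0
    else:
        z = (auc - 0.5) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    sens = np.array([(s[y] >= c).mean() for c in cutoffs])
    spec = np.array([(s[~y] < c).mean() for c in cutoffs])
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # lowest cutoff among ties
    curve = pd.DataFrame({"cutoff": cutoffs, "fpr": 1.0 - spec, "tpr": sens})
    return RocResult(
        auc=auc,
        auc_p=p,
        youden_j=float(j[best]),
        cutoff=float(cutoffs[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        n_pos=n_pos,
        n_neg=n_neg,
        curve=curve,
    )


def predict_dependency(
    expr: ExpressionMatrix,
    genesets: list[GeneSet],
    dep: DependencyTable,
    lineage_filter: str | None = None,
    threshold: float = CHRONOS_THRESHOLD,
    gsva_kwargs: dict | None = None,
) -> pd.DataFrame:
    """GSVA-score each geneset per cell line, binarize dependency, and ROC
    each geneset against the YAP/TAZ and TEAD dependence labels.

    Returns a tidy report with one row per (geneset, label); the RocResult
    objects are in the ``roc`` column. Labels with < 2 dependent lines are
    skipped with a warning.
    """
    if lineage_filter is not None:
        dep = dep.filter_lineage(lineage_filter)
    shared = [c for c in expr.sample_ids if c in set(dep.scores.index)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} cell lines shared between expression and dependency")
    expr = expr.subset_samples(shared)
    labels = binarize_dependency(DependencyTable(dep.scores.loc[shared], None), threshold)
    lines = list(labels.table.index)
    expr = expr.subset_samples(lines)
    if expr.value_space == "tpm":
        expr = log2p1(expr)

    scores: GsvaScores = gsva(expr, genesets, **(gsva_kwargs or {}))
    rows = []
    for label_name, lab in (
        ("YAP/TAZ", labels.dependent_yap_taz),
        ("TEAD", labels.dependent_tead),
    ):
        lab = lab.loc[lines]
        if int(lab.sum()) < 2:
            logger.warning("label %s: <2 dependent lines, ROC skipped", label_name)
            continue
        for gs_name in scores.scores.index:
            r = roc(scores.scores.loc[gs_name, lines], lab)
            rows.append(
                {
                    "geneset": gs_name,
                    "label": label_name,
                    "n_dep": r.n_pos,
                    "n_indep": r.n_neg,
                    "auc": r.auc,
                    "p": r.auc_p,
                    "youden_j": r.youden_j,
                    "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "roc": r,
                }
            )
    return pd.DataFrame(rows)
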