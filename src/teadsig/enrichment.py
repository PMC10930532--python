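"""Gene set enrichment statistics.

Three related statistics built on the weighted Kolmogorov-Smirnov running
sum:

* two-class GSEA with permutation-based NES, nominal p and pooled FDR q,
  selecting phenotype vs geneset permutation by group size (phenotype when
  both groups have >= 8 samples, geneset otherwise);
* preranked %-rank summaries of where a gene falls in a rank-ordered list;
* GSVA single-sample scores from kernel-estimated expression CDFs and a
  symmetric rank statistic random walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import ExpressionMatrix, GeneSet

logger = logging.getLogger("teadsig")

_EPS = 1e-8


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending; ties broken
    lexicographically by symbol for determinism."""

    genes: list[str]
    metric: np.ndarray
    metric_name: str = "signal2noise"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        self.metric = np.asarray(self.metric, dtype=float)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: pd.Series, metric_name: str = "custom") -> "RankedList":
        order = np.lexsort((np.asarray(scores.index), -scores.to_numpy()))
        return cls(list(scores.index[order]), scores.to_numpy()[order], metric_name)


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge_genes: list[str]
    pct_leading_edge: float
    size: int
    perm_type: str = ""


@dataclass
class GsvaScores:
    """Geneset x sample single-sample enrichment scores."""

    scores: pd.DataFrame
    parameters: dict = field(default_factory=dict)


def signal2noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signal-to-noise ratio (mu_a - mu_b) / (sd_a + sd_b) per gene row,
    with each class SD floored at 0.2 * |class mean| (and at a small
    epsilon for means near zero), mirroring the conventional desktop-tool
    floor."""
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)
    sd_a = np.maximum(np.maximum(sd_a, 0.2 * np.abs(mu_a)), _EPS)
    sd_b = np.maximum(np.maximum(sd_b, 0.2 * np.abs(mu_b)), _EPS)
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_genes(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    metric: str = "signal2noise",
) -> RankedList:
    """Rank all genes by a two-class metric, descending (class A enriched
    genes first)."""
    if metric != "signal2noise":
        raise ValueError(f"unknown metric {metric!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("signal2noise requires >= 2 samples per class")
    a = matrix.values[list(group_a)].to_numpy()
    b = matrix.values[list(group_b)].to_numpy()
    s2n = signal2noise(a, b)
    genes = np.asarray(matrix.gene_ids)
    order = np.lexsort((genes, -s2n))
    return RankedList(list(genes[order]), s2n[order], metric)


def _es_curve(metric: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Running sum of the weighted KS walk for one geneset.

    Hits add |metric|^weight normalized by the total hit weight; misses
    subtract 1/(N - N_hits).
    """
    n = len(metric)
    nh = int(hit.sum())
    w = np.abs(metric) ** weight
    hw = np.where(hit, w, 0.0)
    nr = hw.sum()
    if nr <= 0:  # all hit metrics are zero: fall back to equal hit weights
        hw = hit.astype(float)
        nr = float(nh)
    steps = hw / nr
    if n > nh:
        steps = steps - np.where(hit, 0.0, 1.0 / (n - nh))
    return np.cumsum(steps)


def gsea_es(
    ranked: RankedList, geneset: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Enrichment score of one geneset against a ranked list.

    Returns (es, running_sum, leading_edge_genes). The ES is the running
    sum's signed maximum deviation from zero; the leading edge contains the
    hit genes at or before the extremum (at or after it for negative ES).
    """
    members = set(geneset.genes)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    if not hit.any():
        raise ValueError(f"geneset {geneset.name!r} not represented in ranked list")
    run = _es_curve(ranked.metric, hit, weight)
    idx = int(np.abs(run).argmax())
    es = float(run[idx])
    genes = np.asarray(ranked.genes)
    if es >= 0:
        leading = list(genes[: idx + 1][hit[: idx + 1]])
    else:
        leading = list(genes[idx:][hit[idx:]])
    return es, run, leading


def _es_batch(metric: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Vectorized ES for many genesets over one ranked metric.

    ``hits`` is a boolean (n_sets, n_genes) membership matrix in ranked
    order.
    """
    n = hits.shape[1]
    nh = hits.sum(axis=1, keepdims=True)
    w = np.abs(metric) ** weight
    hw = np.where(hits, w, 0.0)
    nr = hw.sum(axis=1, keepdims=True)
    degenerate = (nr <= 0).ravel()
    if degenerate.any():
        hw[degenerate] = hits[degenerate].astype(float)
        nr = hw.sum(axis=1, keepdims=True)
    denom = np.maximum(n - nh, 1)
    steps = hw / nr - np.where(hits, 0.0, 1.0) / denom
    run = np.cumsum(steps, axis=1)
    idx = np.abs(run).argmax(axis=1)
    return run[np.arange(run.shape[0]), idx]


def choose_perm_type(n_a: int, n_b: int) -> str:
    """Phenotype permutation when both groups have >= 8 samples, geneset
    permutation otherwise."""
    return "phenotype" if min(n_a, n_b) >= 8 else "geneset"


def _phenotype_perm_es(
    x: np.ndarray,
    genes: np.ndarray,
    n_a: int,
    hits_by_gene: np.ndarray,
    nperm: int,
    weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_sets, nperm) ES under random relabelling of samples."""
    n_sets = hits_by_gene.shape[0]
    n_total = x.shape[1]
    out = np.empty((n_sets, nperm))
    for p in range(nperm):
        cols = rng.permutation(n_total)
        s2n = signal2noise(x[:, cols[:n_a]], x[:, cols[n_a:]])
        order = np.lexsort((genes, -s2n))
        out[:, p] = _es_batch(s2n[order], hits_by_gene[:, order], weight)
    return out


def _geneset_perm_es(
    metric_sorted: np.ndarray,
    sizes: list[int],
    nperm: int,
    weight: float,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Null ES per geneset size from random gene subsets of the ranked
    universe (one shared pool per size)."""
    n = len(metric_sorted)
    out: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        picks = np.argsort(rng.random((nperm, n)), axis=1)[:, :k]
        hits = np.zeros((nperm, n), dtype=bool)
        np.put_along_axis(hits, picks, True, axis=1)
        out[k] = _es_batch(metric_sorted, hits, weight)
    return out


def _normalize(es: float | np.ndarray, perm: np.ndarray) -> tuple[float | np.ndarray, float, float]:
    """Scale ES by the mean |permutation ES| of matching sign."""
    pos = perm[perm >= 0]
    neg = perm[perm < 0]
    mean_pos = pos.mean() if len(pos) else np.nan
    mean_neg = np.abs(neg).mean() if len(neg) else np.nan
    es = np.asarray(es, dtype=float)
    nes = np.where(es >= 0, es / mean_pos, es / mean_neg)
    return (float(nes) if nes.ndim == 0 else nes), mean_pos, mean_neg


def gsea(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    genesets: list[GeneSet],
    nperm: int = 1000,
    perm_type: str = "auto",
    weight: float = 1.0,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Two-class GSEA over a collection of genesets.

    Nominal p compares |ES| with same-sign permutation ES (add-one
    smoothed); NES divides ES by the mean same-sign permutation |ES|; FDR q
    uses the pooled positive/negative NES scheme. Deterministic given
    ``seed``.
    """
    if nperm < 10:
        raise ValueError("nperm must be >= 10")
    if not genesets:
        raise ValueError("no genesets supplied")
    if perm_type == "auto":
        perm_type = choose_perm_type(len(group_a), len(group_b))
    if perm_type not in ("phenotype", "geneset"):
        raise ValueError(f"unknown perm_type {perm_type!r}")
    rng = np.random.default_rng(seed)

    ranked = rank_genes(matrix, group_a, group_b)
    genes_sorted = np.asarray(ranked.genes)
    kept = [gs.intersect(genes_sorted) for gs in genesets]
    pos_of = {g: i for i, g in enumerate(genes_sorted)}
    hits = np.zeros((len(kept), len(genes_sorted)), dtype=bool)
    for i, gs in enumerate(kept):
        hits[i, [pos_of[g] for g in gs.genes]] = True

    observed = [gsea_es(ranked, gs, weight) for gs in kept]

    if perm_type == "phenotype":
        x = matrix.values[list(group_a) + list(group_b)].to_numpy()
        gene_arr = np.asarray(matrix.gene_ids)
        member = np.zeros((len(kept), len(gene_arr)), dtype=bool)
        gene_pos = {g: i for i, g in enumerate(gene_arr)}
        for i, gs in enumerate(kept):
            member[i, [gene_pos[g] for g in gs.genes]] = True
        perm_es = _phenotype_perm_es(x, gene_arr, len(group_a), member, nperm, weight, rng)
    else:
        pools = _geneset_perm_es(ranked.metric, [len(gs) for gs in kept], nperm, weight, rng)
        perm_es = np.vstack([pools[len(gs)] for gs in kept])

    nes_obs = np.empty(len(kept))
    nominal_p = np.empty(len(kept))
    perm_nes_rows: list[np.ndarray] = []
    for i, (es, _, _) in enumerate(observed):
        perm = perm_es[i]
        nes_i, _, _ = _normalize(es, perm)
        nes_obs[i] = nes_i
        same = perm[perm >= 0] if es >= 0 else perm[perm < 0]
        nominal_p[i] = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
        perm_nes_rows.append(np.asarray(_normalize(perm, perm)[0]))
    pooled = np.concatenate(perm_nes_rows)
    pooled = pooled[np.isfinite(pooled)]

    results = []
    for i, (gs, (es, _, leading)) in enumerate(zip(kept, observed)):
        q = _fdr_q(nes_obs[i], nes_obs, pooled)
        results.append(
            EnrichmentResult(
                name=gs.name,
                es=es,
                nes=float(nes_obs[i]),
                nominal_p=float(nominal_p[i]),
                fdr_q=q,
                leading_edge_genes=leading,
                pct_leading_edge=100.0 * len(leading) / len(gs),
                size=len(gs),
                perm_type=perm_type,
            )
        )
    return results


def _fdr_q(nes: float, all_obs: np.ndarray, pooled_perm: np.ndarray) -> float:
    """Pooled positive/negative FDR q for one observed NES."""
    if not np.isfinite(nes):
        return 1.0
    obs = all_obs[np.isfinite(all_obs)]
    if nes >= 0:
        perm_side = pooled_perm[pooled_perm >= 0]
        obs_side = obs[obs >= 0]
        numer = (perm_side >= nes).mean() if len(perm_side) else 1.0
        denom = (obs_side >= nes).mean() if len(obs_side) else 1.0
    else:
        perm_side = pooled_perm[pooled_perm < 0]
        obs_side = obs[obs < 0]
        numer = (perm_side <= nes).mean() if len(perm_side) else 1.0
        denom = (obs_side <= nes).mean() if len(obs_side) else 1.0
    if denom == 0:
        return 1.0
    return float(min(1.0, numer / denom))


def percent_rank(ranked: RankedList, genes: list[str] | GeneSet) -> pd.DataFrame:
    """Percent rank (100 * rank / N, rank 1 = most activity-enriched) and
    bin (top <= 15, bottom >= 85, mid in between, absent if the gene is not
    in the list) for each queried gene."""
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    if isinstance(genes, GeneSet):
        genes = list(genes.genes)
    n = len(ranked)
    pos = {g: i + 1 for i, g in enumerate(ranked.genes)}
    rows = []
    for g in genes:
        if g in pos:
            pct = 100.0 * pos[g] / n
            if pct <= 15.0:
                b = "top"
            elif pct >= 85.0:
                b = "bottom"
            else:
                b = "mid"
            rows.append((g, pct, b))
        else:
            rows.append((g, np.nan, "absent"))
    return pd.DataFrame(rows, columns=["gene", "pct", "bin"]).set_index("gene")


# ---------------------------------------------------------------------------
# GSVA


def _kernel_cdf(x: np.ndarray, kcdf: str) -> np.ndarray:
    """Per-gene cumulative density estimates across samples.

    ``gaussian`` uses a Gaussian kernel with bandwidth s_i / 4 per gene;
    ``ecdf`` uses the empirical CDF (pure ranks). Zero-variance genes fall
    back to an epsilon bandwidth, which degenerates to the ECDF step.
    """
    g, n = x.shape
    if kcdf == "ecdf":
        order = np.argsort(x, axis=1, kind="stable")
        ranks = np.empty_like(x)
        np.put_along_axis(ranks, order, np.arange(1, n + 1, dtype=float), axis=1)
        # average ranks for ties
        out = np.empty_like(x)
        for i in range(g):
            _, inv, counts = np.unique(x[i], return_inverse=True, return_counts=True)
            csum = np.concatenate(([0], np.cumsum(counts)))
            avg = (csum[:-1] + (counts + 1) / 2.0)[inv]
            out[i] = avg / n
        return out
    if kcdf != "gaussian":
        raise ValueError(f"unknown kcdf {kcdf!r}")
    h = x.std(axis=1, ddof=1) / 4.0
    h = np.maximum(h, _EPS)
    out = np.empty_like(x)
    chunk = max(1, int(2e7 // (n * n)))
    for lo in range(0, g, chunk):
        hi = min(lo + chunk, g)
        diff = (x[lo:hi, :, None] - x[lo:hi, None, :]) / h[lo:hi, None, None]
        out[lo:hi] = ndtr(diff).mean(axis=2)
    return out


def gsva(
    matrix: ExpressionMatrix,
    genesets: list[GeneSet],
    kcdf: str = "gaussian",
    tau: float = 1.0,
    mx_diff: bool = True,
) -> GsvaScores:
    """Single-sample enrichment scores per geneset per sample.

    Per gene, expression is turned into a kernel CDF estimate across
    samples; per sample, genes are ranked by that estimate (descending,
    symbol tie-break) and the symmetric rank statistic |N/2 - r| drives a
    KS-like random walk over the geneset. With ``mx_diff`` the score is the
    maximum positive deviation plus the minimum negative deviation of the
    walk; otherwise the signed maximum deviation.
    """
    if matrix.n_samples < 3:
        raise ValueError("gsva requires >= 3 samples")
    if not genesets:
        raise ValueError("no genesets supplied")
    x = matrix.values.to_numpy()
    genes = np.asarray(matrix.gene_ids)
    g, n_samp = x.shape
    z = _kernel_cdf(x, kcdf)

    kept = [gs.intersect(genes) for gs in genesets]
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    member = np.zeros((len(kept), g), dtype=bool)
    for i, gs in enumerate(kept):
        member[i, [gene_pos[gname] for gname in gs.genes]] = True

    scores = np.empty((len(kept), n_samp))
    half = g / 2.0
    for j in range(n_samp):
        order = np.lexsort((genes, -z[:, j]))  # rank 1 = highest CDF estimate
        ranks = np.arange(1, g + 1, dtype=float)
        stat = np.abs(half - ranks) ** tau
        hits = member[:, order]
        hw = np.where(hits, stat, 0.0)
        nr = hw.sum(axis=1, keepdims=True)
        nh = hits.sum(axis=1, keepdims=True)
        steps = hw / nr - np.where(hits, 0.0, 1.0) / np.maximum(g - nh, 1)
        run = np.cumsum(steps, axis=1)
        if mx_diff:
            scores[:, j] = np.maximum(run.max(axis=1), 0.0) + np.minimum(run.min(axis=1), 0.0)
        else:
            idx = np.abs(run).argmax(axis=1)
            scores[:, j] = run[np.arange(run.shape[0]), idx]
    frame = pd.DataFrame(scores, index=[gs.name for gs in kept], columns=matrix.sample_ids)
    return GsvaScores(frame, {"kcdf": kcdf, "tau": tau, "mx_diff": mx_diff})
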