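"""Consensus up/down signature derivation from oriented DE contrasts.

A signature gene must be regulated in the anchor contrast and in at least
``min_support`` of the supporting contrasts, in the same activity-oriented
direction everywhere. Contrasts may be measured under pathway activation
(e.g. constitutively active YAP) or depletion (siRNA knockdown); tables are
re-oriented so that a positive log2 fold change always means "higher with
YAP/TAZ activity" before thresholds are applied.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, GeneSet, log2p1, normalize_symbol

logger = logging.getLogger("teadsig")

ORIENTATIONS = ("activation", "depletion")


@dataclass
class DETable:
    """One differential-expression contrast.

    ``table`` is indexed by gene symbol with columns ``log2fc``, ``p``,
    ``fdr`` and ``detected`` (bool). ``orientation`` records whether the
    contrast raised ("activation") or lowered ("depletion") YAP/TAZ
    activity; it is fixed before any sign flip.
    """

    contrast_id: str
    orientation: str
    table: pd.DataFrame
    oriented: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        required = {"log2fc", "p", "fdr", "detected"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DETable missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate genes in DETable")
        fdr = self.table["fdr"].dropna()
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValueError("fdr outside [0, 1]")


@dataclass
class GeneSignature:
    """Named up and down gene sets plus, per gene, the contrasts that
    supported its inclusion. A side with no consensus genes is ``None``."""

    up: GeneSet | None
    down: GeneSet | None
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        up = set(self.up.genes) if self.up else set()
        down = set(self.down.genes) if self.down else set()
        overlap = up & down
        if overlap:
            raise ValueError(f"up/down overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> tuple[str, ...]:
        up = self.up.genes if self.up else ()
        down = self.down.genes if self.down else ()
        return up + down


def standin_de(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
    contrast_id: str = "standin",
    orientation: str = "activation",
) -> DETable:
    """Simple DE test for synthetic end-to-end runs.

    log2fc compares TPM group means with a pseudocount; p-values come from
    Welch's two-sample t-test on log2(1+TPM) values; FDR is
    Benjamini-Hochberg over all detected genes. Real-data analyses consume
    externally produced DE tables instead.
    """
    if matrix.value_space != "tpm":
        raise ValueError("standin_de expects TPM values")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix.values[group_a].to_numpy()
    b = matrix.values[group_b].to_numpy()
    log2fc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(b.mean(axis=1) + pseudocount)
    la, lb = np.log2(1.0 + a), np.log2(1.0 + b)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both-groups genes
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "detected": True},
        index=matrix.values.index,
    )
    return DETable(contrast_id=contrast_id, orientation=orientation, table=table)


def orient(de: DETable) -> DETable:
    """Flip depletion contrasts so positive log2fc means YAP/TAZ-induced."""
    if de.oriented:
        raise ValueError(f"contrast {de.contrast_id!r} is already oriented")
    table = de.table.copy()
    if de.orientation == "depletion":
        table["log2fc"] = -table["log2fc"]
    return replace(de, table=table, oriented=True)


def call_regulated(
    de: DETable, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> tuple[set[str], set[str]]:
    """Up/down calls at strict fold-change and FDR cutoffs (>2-fold,
    FDR<0.05 by default; boundary genes are excluded)."""
    if not de.oriented:
        raise ValueError("call_regulated requires an oriented DETable")
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    t = de.table[de.table["detected"].astype(bool)]
    lfc_cut = np.log2(fc_threshold)
    sig = t["fdr"] < fdr_threshold
    up = set(t.index[sig & (t["log2fc"] > lfc_cut)])
    down = set(t.index[sig & (t["log2fc"] < -lfc_cut)])
    return up, down


def derive_consensus(
    anchor: DETable,
    supports: list[DETable],
    min_support: int = 2,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    name: str = "YAP_TAZ",
) -> GeneSignature:
    """Consensus signature: regulated in the anchor and in >= ``min_support``
    supporting contrasts, all in the same oriented direction.

    A gene regulated one way in the anchor but the opposite way in any
    support is dropped entirely (direction consistency). Genes absent from
    a support table count as non-supporting, not contradicting.
    """
    if not supports:
        raise ValueError("supports must be non-empty")
    if min_support > len(supports):
        raise ValueError(f"min_support={min_support} exceeds {len(supports)} supports")
    anchor_up, anchor_down = call_regulated(anchor, fc_threshold, fdr_threshold)
    calls = [call_regulated(s, fc_threshold, fdr_threshold) for s in supports]
    ids = [s.contrast_id for s in supports]

    def consensus(anchor_set: set[str], side: int) -> tuple[list[str], dict[str, frozenset[str]]]:
        kept: list[str] = []
        prov: dict[str, frozenset[str]] = {}
        for gene in sorted(anchor_set):
            same = [cid for cid, c in zip(ids, calls) if gene in c[side]]
            other = [cid for cid, c in zip(ids, calls) if gene in c[1 - side]]
            if other:
                logger.info("consensus: %s dropped, opposite direction in %s", gene, other)
                continue
            if len(same) >= min_support:
                kept.append(gene)
                prov[gene] = frozenset([anchor.contrast_id, *same])
        return kept, prov

    up_genes, up_prov = consensus(anchor_up, 0)
    down_genes, down_prov = consensus(anchor_down, 1)
    if not up_genes or not down_genes:
        logger.warning("consensus signature: %d up / %d down genes", len(up_genes), len(down_genes))
    up = GeneSet(f"{name}_UP", "consensus up", tuple(up_genes)) if up_genes else None
    down = GeneSet(f"{name}_DOWN", "consensus down", tuple(down_genes)) if down_genes else None
    return GeneSignature(up=up, down=down, provenance={**up_prov, **down_prov})


def venn_counts(sets: list[tuple[str, set[str]]]) -> dict[tuple[str, ...], int]:
    """Counts for every membership region of 2-4 labelled sets.

    Keys are sorted tuples of the labels a region belongs to; regions
    partition the union, so counts sum to the union size.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn_counts supports 2-4 sets")
    labels = [lab for lab, _ in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate set labels")
    members = {lab: set(s) for lab, s in sets}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(members[lab] for lab in combo))
            outside = set.union(set(), *(members[lab] for lab in labels if lab not in combo))
            counts[tuple(sorted(combo))] = len(inside - outside)
    return counts
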