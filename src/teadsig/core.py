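"""Core data model and elementary transforms.

The pipeline's shared currency is a genes x samples expression matrix
annotated with the space its values live in (``tpm``, ``log2p1`` or
``zscore``), plus small value types for gene sets, a simplified gene model
used by peak annotation, and qPCR Ct tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("teadsig")

VALUE_SPACES = ("tpm", "log2p1", "zscore")

_DEPMAP_HEADER = re.compile(r"^\s*(?P<symbol>[^()\s]+)\s*\((?P<entrez>[^()]*)\)\s*$")


def normalize_symbol(symbol: str, *, depmap: bool = False) -> str:
    """Normalize a gene symbol: upper-case, strip whitespace, and in the
    DepMap dialect strip the trailing ``(ENTREZID)`` annotation.

    >>> normalize_symbol("WWTR1 (25937)", depmap=True)
    'WWTR1'
    """
    s = str(symbol).strip()
    if depmap:
        m = _DEPMAP_HEADER.match(s)
        if m:
            s = m.group("symbol")
    return s.upper()


def normalize_symbols(symbols: Iterable[str], *, depmap: bool = False) -> list[str]:
    return [normalize_symbol(s, depmap=depmap) for s in symbols]


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        norm: list[str] = []
        seen: set[str] = set()
        dupes = 0
        for g in self.genes:
            ng = normalize_symbol(g)
            if ng in seen:
                dupes += 1
                continue
            seen.add(ng)
            norm.append(ng)
        if dupes:
            logger.warning("gene set %r: dropped %d duplicate symbols", self.name, dupes)
        if not norm:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(norm))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in set(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        """Restrict to genes present in ``universe`` (order preserved)."""
        uni = set(universe)
        kept = tuple(g for g in self.genes if g in uni)
        dropped = len(self.genes) - len(kept)
        if dropped:
            logger.info("gene set %r: %d genes absent from matrix, dropped", self.name, dropped)
        if not kept:
            raise ValueError(f"gene set {self.name!r} not represented in the matrix")
        return GeneSet(self.name, self.description, kept)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus optional per-sample metadata.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns. ``sample_meta``, when present, is indexed by sample id with at
    least the columns ``phenotype_label`` and ``lineage``.
    """

    values: pd.DataFrame
    value_space: str = "tpm"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.value_space not in VALUE_SPACES:
            raise ValueError(f"unknown value_space {self.value_space!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        self.values = self.values.astype(float)
        if self.value_space == "tpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        if self.sample_meta is not None:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing samples: {list(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype(self, label: str) -> list[str]:
        """Sample ids carrying a phenotype label."""
        if self.sample_meta is None:
            raise ValueError("matrix has no sample metadata")
        mask = self.sample_meta["phenotype_label"] == label
        return list(self.sample_meta.index[mask])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(samples)]
        return ExpressionMatrix(self.values[list(samples)], self.value_space, meta)


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(1 + x) of a TPM matrix."""
    if matrix.value_space != "tpm":
        raise ValueError(f"log2p1 expects tpm values, got {matrix.value_space!r}")
    vals = matrix.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative values in TPM matrix")
    out = pd.DataFrame(np.log2(1.0 + vals), index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=out, value_space="log2p1")


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores across samples (sample SD, n-1 denominator).

    Constant rows map to all-zero rows so that downstream correlations and
    heatmaps stay finite.
    """
    if matrix.value_space != "log2p1":
        raise ValueError(f"zscore_rows expects log2p1 values, got {matrix.value_space!r}")
    if matrix.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = matrix.values.to_numpy()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd, z.shape) == 0] = 0.0
    out = pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=out, value_space="zscore")


def inverse_log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform log2(1 + x) values to TPM (2**x - 1)."""
    if matrix.value_space != "log2p1":
        raise ValueError("inverse_log2p1 expects log2p1 values")
    out = np.exp2(matrix.values) - 1.0
    return replace(matrix, values=out.clip(lower=0.0), value_space="tpm")


# ---------------------------------------------------------------------------
# Gene model (simplified, single transcript per gene)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int  # span start, 0-based
    end: int  # span end, half-open
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty span")
        for s, e in (*self.exons, *self.utr5, *self.utr3):
            if not s < e:
                raise ValueError(f"{self.gene_id}: empty interval [{s},{e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: interval [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        """Transcription start site: span start on +, last base on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneModel:
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in gene model")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for r in self.records:
            out.setdefault(r.chrom, []).append(r)
        return out

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrTable:
    """Ct values indexed by (sample, gene), with the reference gene and the
    calibrator sample used for relative quantification."""

    ct: pd.Series  # MultiIndex (sample, gene) -> Ct
    reference_gene: str
    control_sample: str

    def __post_init__(self) -> None:
        idx = self.ct.index
        if idx.nlevels != 2:
            raise ValueError("ct must be indexed by (sample, gene)")
        samples = idx.get_level_values(0).unique()
        genes = idx.get_level_values(1).unique()
        if self.reference_gene not in genes:
            raise ValueError(f"reference gene {self.reference_gene!r} absent")
        if self.control_sample not in samples:
            raise ValueError(f"control sample {self.control_sample!r} absent")
        if not np.isfinite(self.ct.dropna().to_numpy()).all():
            raise ValueError("non-finite Ct values")


def ddct_fold_change(q: QpcrTable) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    dCt = Ct_gene - Ct_reference per sample; ddCt = dCt_sample -
    dCt_control; fold change = 2 ** (-ddCt). The control sample maps to
    fold 1 exactly. Pairs with a missing Ct (gene or reference) are omitted
    with a warning.
    """
    wide = q.ct.unstack(level=1)  # samples x genes
    if q.reference_gene not in wide.columns:
        raise ValueError(f"reference gene {q.reference_gene!r} absent")
    dct = wide.sub(wide[q.reference_gene], axis=0)
    ddct = dct.sub(dct.loc[q.control_sample], axis=1)
    fold = np.exp2(-ddct)
    n_missing = int(fold.isna().to_numpy().sum())
    if n_missing:
        logger.warning("ddct_fold_change: %d (sample, gene) pairs missing Ct, omitted", n_missing)
    fold = fold.drop(columns=[q.reference_gene])
    return fold
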