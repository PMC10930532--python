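"""File readers and writers for the pipeline's interchange formats.

Expression matrices travel as TSV/CSV (first column gene symbol, header
row sample ids) with an optional phenotype sidecar TSV; genesets as GMT;
DE contrasts as TSV with a YAML sidecar for contrast metadata; dependency
scores as CSV in the DepMap header dialect; peaks as BED; the simplified
gene model as TSV. Minimal GCT/CLS writers are provided for
interoperability with external GSEA tooling.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ExpressionMatrix, GeneModel, GeneRecord, GeneSet, QpcrTable, normalize_symbol
from .dependency import DependencyTable
from .peaks import Peak
from .signature import DETable, GeneSignature

logger = logging.getLogger("teadsig")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path: str | Path,
    dialect: str = "plain",
    sep: str | None = None,
    on_duplicate: str = "fail",
    phenotype_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``plain``: genes x samples TSV/CSV of TPM values. ``depmap``: the
    DepMap wide CSV (rows cell lines, columns "SYMBOL (ENTREZID)") whose
    values are already log2(1+TPM); it is transposed to genes x samples and
    not re-transformed. Duplicate symbols after normalization either raise
    (``on_duplicate='fail'``) or keep the first occurrence with a warning
    (``'first'``).
    """
    path = Path(path)
    if dialect not in ("plain", "depmap"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if dialect == "depmap":
        df = df.T  # rows were cell lines
        df.index = [normalize_symbol(g, depmap=True) for g in df.index]
        space = "log2p1"
    else:
        df.index = [normalize_symbol(g) for g in df.index]
        space = "tpm"
    if pd.Index(df.index).has_duplicates:
        dupes = sorted(pd.Index(df.index)[pd.Index(df.index).duplicated()].unique())
        if on_duplicate == "fail":
            raise ValueError(f"duplicate gene symbols after normalization: {dupes[:5]}")
        logger.warning("duplicate symbols %s: keeping first occurrence", dupes[:5])
        df = df[~pd.Index(df.index).duplicated(keep="first")]
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(f"non-numeric value at gene {gene!r}, sample {sample!r}") from None
    meta = read_phenotypes(phenotype_path) if phenotype_path else None
    return ExpressionMatrix(df, value_space=space, sample_meta=meta)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype sidecar: TSV with columns sample_id, phenotype_label,
    lineage (lineage optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "phenotype_label" not in df.columns:
        raise ValueError("phenotype sidecar needs sample_id and phenotype_label columns")
    if "lineage" not in df.columns:
        df["lineage"] = ""
    return df.set_index("sample_id")


def write_phenotypes(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT genesets


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            sets.append(GeneSet(name, desc, tuple(g for g in genes if g.strip())))
    return sets


def write_gmt(genesets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# DE tables


def read_de_table(path: str | Path, meta_path: str | Path | None = None) -> DETable:
    """DE contrast TSV (gene, log2fc, p, fdr, detected) plus a YAML sidecar
    carrying contrast_id / orientation. Without a sidecar, looks for
    ``<path>.yaml``."""
    path = Path(path)
    if meta_path is None:
        candidate = path.with_suffix(path.suffix + ".yaml")
        meta_path = candidate if candidate.exists() else None
    meta = {}
    if meta_path is not None:
        meta = yaml.safe_load(Path(meta_path).read_text()) or {}
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index = [normalize_symbol(g) for g in df.index]
    if "detected" not in df.columns:
        df["detected"] = True
    df["detected"] = df["detected"].astype(bool)
    return DETable(
        contrast_id=str(meta.get("contrast_id", path.stem)),
        orientation=str(meta.get("orientation", "activation")),
        table=df,
        oriented=bool(meta.get("oriented", False)),
    )


def write_de_table(de: DETable, path: str | Path) -> None:
    path = Path(path)
    de.table.to_csv(path, sep="\t", index_label="gene")
    meta = {"contrast_id": de.contrast_id, "orientation": de.orientation, "oriented": de.oriented}
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))


def write_signature(sig: GeneSignature, gmt_path: str | Path, provenance_path: str | Path) -> None:
    sets = [s for s in (sig.up, sig.down) if s is not None]
    write_gmt(sets, gmt_path)
    rows = [
        {"gene": g, "direction": "up" if (sig.up and g in sig.up.genes) else "down",
         "contrasts": ",".join(sorted(cids))}
        for g, cids in sorted(sig.provenance.items())
    ]
    pd.DataFrame(rows, columns=["gene", "direction", "contrasts"]).to_csv(
        provenance_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Dependency tables


def read_dependency(
    path: str | Path, lineage_path: str | Path | None = None
) -> DependencyTable:
    """Dependency CSV: rows cell lines, columns gene symbols (DepMap
    "SYMBOL (ENTREZID)" headers accepted). Optional lineage sidecar CSV
    with columns cell_line, lineage."""
    df = pd.read_csv(path, index_col=0)
    df.columns = [normalize_symbol(c, depmap=True) for c in df.columns]
    lineage = None
    if lineage_path is not None:
        lin = pd.read_csv(lineage_path)
        if "cell_line" not in lin.columns or "lineage" not in lin.columns:
            raise ValueError("lineage sidecar needs cell_line and lineage columns")
        lineage = lin.set_index("cell_line")["lineage"]
    return DependencyTable(df, lineage)


def write_dependency(dep: DependencyTable, path: str | Path,
                     lineage_path: str | Path | None = None) -> None:
    dep.scores.to_csv(path, index_label="cell_line")
    if lineage_path is not None and dep.lineage is not None:
        dep.lineage.rename("lineage").to_csv(lineage_path, index_label="cell_line")


# ---------------------------------------------------------------------------
# qPCR


def read_qpcr(path: str | Path, reference_gene: str, control_sample: str) -> QpcrTable:
    """Long-format qPCR TSV with columns sample, gene, Ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "Ct"}
    if not required <= set(df.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    ct = df.set_index(["sample", "gene"])["Ct"].astype(float)
    return QpcrTable(ct, reference_gene=reference_gene, control_sample=control_sample)


# ---------------------------------------------------------------------------
# BED peaks and gene model


def read_bed(path: str | Path) -> list[Peak]:
    """3-6 column BED, 0-based half-open."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 fields")
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            peaks.append(Peak(fields[0], int(fields[1]), int(fields[2]), name, score))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t{p.score:g}\t.\n")


def read_gene_model(path: str | Path) -> GeneModel:
    """Gene model TSV: gene_id, chrom, strand, start, end, exon_starts,
    exon_ends (comma-separated lists)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "start", "end", "exon_starts", "exon_ends"}
    if not required <= set(df.columns):
        raise ValueError(f"gene model TSV needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        starts = [int(v) for v in str(row.exon_starts).rstrip(",").split(",") if v]
        ends = [int(v) for v in str(row.exon_ends).rstrip(",").split(",") if v]
        if len(starts) != len(ends):
            raise ValueError(f"{row.gene_id}: exon_starts/exon_ends length mismatch")
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id), chrom=str(row.chrom), strand=str(row.strand),
                start=int(row.start), end=int(row.end),
                exons=tuple(zip(starts, ends)),
            )
        )
    return GeneModel(records)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    rows = []
    for r in model:
        rows.append(
            {
                "gene_id": r.gene_id, "chrom": r.chrom, "strand": r.strand,
                "start": r.start, "end": r.end,
                "exon_starts": ",".join(str(s) for s, _ in r.exons),
                "exon_ends": ",".join(str(e) for _, e in r.exons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal GCT / CLS writers (courtesy interop with external GSEA tooling)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in matrix.values.iterrows():
            fh.write(gene + "\tna\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    classes = list(dict.fromkeys(labels))
    idx = {c: i for i, c in enumerate(classes)}
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(idx[l]) for l in labels) + "\n")
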