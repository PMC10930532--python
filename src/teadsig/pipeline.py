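"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (signature -> enrichment -> dependency_roc
-> cohort_correlation -> peak_annotation); each stage reads plain-text
inputs, writes plain TSV/JSON reports into the output directory, and the
run manifest records the seed, input hashes and per-stage outputs. All
stochastic stages take explicit seeds from the config; there is no global
RNG state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .cohort import assign_groups, group_compare, similarity_matrix, spearman_vs_marker, strong_correlation_venn
from .core import GeneSet, log2p1
from .dependency import predict_dependency
from .enrichment import gsea
from .peaks import annotate_peaks, gene_peak_matrix
from .signature import derive_consensus, orient

logger = logging.getLogger("teadsig")

STAGE_ORDER = ("signature", "enrichment", "dependency_roc", "cohort_correlation", "peak_annotation")


@dataclass
class RunConfig:
    """Paths, thresholds and seed for a pipeline run. Threshold defaults
    equal the analysis' printed settings (fold change > 2, FDR < 0.05,
    Chronos <= -0.65, TSS window +/- 1 kb, high/low split at 1 SD, 1000
    permutations)."""

    stages: list[str]
    out_dir: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    min_support: int = 2
    chronos_threshold: float = -0.65
    tss_window: int = 1000
    downstream_window: int = 3000
    high_low_k: float = 1.0
    nperm: int = 1000
    signature_name: str = "YAP_TAZ"
    lineage_filter: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def require(self, stage: str, *keys: str) -> list[str]:
        missing = [k for k in keys if k not in self.inputs]
        if missing:
            raise ValueError(f"stage {stage!r} requires missing inputs: {missing}")
        paths = [self.inputs[k] for k in keys]
        absent = [p for p in paths if isinstance(p, str) and not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"stage {stage!r}: input files not found: {absent}")
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    for key, value in config.inputs.items():
        if isinstance(value, str) and Path(value).exists():
            manifest["inputs"][key] = _sha256(value)

    signature_sets: list[GeneSet] | None = None
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        outputs: dict[str, str] = {}

        if stage == "signature":
            anchor_path, = config.require(stage, "anchor_de")
            support_paths = config.inputs.get("support_des") or []
            if not support_paths:
                raise ValueError("stage 'signature' requires inputs: ['support_des']")
            anchor = tio.read_de_table(anchor_path)
            supports = [tio.read_de_table(p) for p in support_paths]
            anchor = anchor if anchor.oriented else orient(anchor)
            supports = [s if s.oriented else orient(s) for s in supports]
            sig = derive_consensus(
                anchor, supports, min_support=config.min_support,
                fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold,
                name=config.signature_name,
            )
            gmt = out / "signature.gmt"
            prov = out / "signature_provenance.tsv"
            tio.write_signature(sig, gmt, prov)
            signature_sets = [s for s in (sig.up, sig.down) if s is not None]
            outputs = {"gmt": str(gmt), "provenance": str(prov)}

        elif stage == "enrichment":
            expr_path, pheno_path = config.require(stage, "expression", "phenotypes")
            matrix = tio.read_expression(expr_path, phenotype_path=pheno_path)
            genesets = _genesets(config, signature_sets)
            labels = matrix.sample_meta["phenotype_label"].unique()
            if len(labels) != 2:
                raise ValueError(f"enrichment needs exactly 2 phenotype labels, got {list(labels)}")
            a, b = sorted(labels)
            results = gsea(
                matrix if matrix.value_space != "tpm" else log2p1(matrix),
                matrix.phenotype(a), matrix.phenotype(b), genesets,
                nperm=config.nperm, seed=config.seed,
            )
            report = pd.DataFrame(
                [
                    {
                        "geneset": r.name, "size": r.size, "es": r.es, "nes": r.nes,
                        "nominal_p": r.nominal_p, "fdr_q": r.fdr_q,
                        "pct_leading_edge": r.pct_leading_edge, "perm_type": r.perm_type,
                        "leading_edge": ",".join(r.leading_edge_genes),
                    }
                    for r in results
                ]
            )
            path = out / "gsea_report.tsv"
            report.to_csv(path, sep="\t", index=False)
            outputs = {"report": str(path)}

        elif stage == "dependency_roc":
            expr_path, dep_path = config.require(stage, "cell_line_expression", "dependency_csv")
            dialect = config.inputs.get("cell_line_dialect", "plain")
            matrix = tio.read_expression(expr_path, dialect=dialect)
            dep = tio.read_dependency(dep_path, config.inputs.get("lineage_csv"))
            genesets = _genesets(config, signature_sets)
            report = predict_dependency(
                matrix, genesets, dep,
                lineage_filter=config.lineage_filter, threshold=config.chronos_threshold,
            )
            path = out / "roc_report.tsv"
            report.drop(columns=["roc"]).to_csv(path, sep="\t", index=False)
            outputs = {"report": str(path)}
            for _, row in report.iterrows():
                label = row["label"].replace("/", "")
                cpath = out / f"roc_curve_{row['geneset']}_{label}.tsv"
                row["roc"].curve.to_csv(cpath, sep="\t", index=False)
                outputs[f"curve_{row['geneset']}_{label}"] = str(cpath)

        elif stage == "cohort_correlation":
            (cohort_path,) = config.require(stage, "cohort_expression")
            markers = config.inputs.get("markers") or ["CTGF", "CYR61"]
            matrix = tio.read_expression(cohort_path)
            whitelist = config.inputs.get("sample_whitelist")
            if whitelist:
                keep = [s.strip() for s in Path(whitelist).read_text().splitlines() if s.strip()]
                matrix = matrix.subset_samples(keep)
            matrix = log2p1(matrix)
            genesets = _genesets(config, signature_sets)
            genes = sorted({g for gs in genesets for g in gs.genes if g in set(matrix.gene_ids)})
            reports = {}
            for i, marker in enumerate(markers):
                grouping = assign_groups(matrix, marker, k=config.high_low_k)
                (out / f"groups_{marker}.tsv").write_text(
                    grouping.groups.rename("group").to_csv(sep="\t")
                )
                cmp_table = group_compare(matrix, grouping, genes)
                cmp_table.to_csv(out / f"group_compare_{marker}.tsv", sep="\t")
                rep = spearman_vs_marker(
                    matrix, marker, genes, nperm=config.nperm, seed=config.seed + i
                )
                rep.table.to_csv(out / f"correlation_{marker}.tsv", sep="\t")
                sim = similarity_matrix(matrix, genes, marker)
                sim.matrix.to_csv(out / f"similarity_{marker}.tsv", sep="\t")
                reports[marker] = rep
                outputs[f"correlation_{marker}"] = str(out / f"correlation_{marker}.tsv")
            if len(markers) >= 2:
                venn = strong_correlation_venn(reports[markers[0]], reports[markers[1]])
                vpath = out / "strong_correlation_venn.json"
                vpath.write_text(json.dumps(venn, indent=1))
                outputs["venn"] = str(vpath)

        elif stage == "peak_annotation":
            (model_path,) = config.require(stage, "gene_model")
            bed_by_dataset = config.inputs.get("peaks") or {}
            if not bed_by_dataset:
                raise ValueError("stage 'peak_annotation' requires inputs: ['peaks']")
            model = tio.read_gene_model(model_path)
            annotations = {}
            rows = []
            for dataset, bed in sorted(bed_by_dataset.items()):
                peaks = tio.read_bed(bed)
                annos = annotate_peaks(
                    peaks, model,
                    tss_window=config.tss_window, downstream_window=config.downstream_window,
                )
                annotations[dataset] = annos
                for a in annos:
                    rows.append(
                        {
                            "dataset": dataset, "chrom": a.peak.chrom, "start": a.peak.start,
                            "end": a.peak.end, "category": a.category,
                            "gene": a.gene_id or "", "nearest_gene": a.nearest_gene or "",
                            "distance_to_tss": a.distance_to_tss,
                        }
                    )
            apath = out / "peak_annotations.tsv"
            pd.DataFrame(rows).to_csv(apath, sep="\t", index=False)
            genes = config.inputs.get("peak_matrix_genes")
            if genes is None:
                sig_sets = _genesets(config, signature_sets)
                genes = sorted({g for gs in sig_sets for g in gs.genes})
            mat = gene_peak_matrix(annotations, list(genes))
            mpath = out / "gene_peak_matrix.tsv"
            mat.to_csv(mpath, sep="\t")
            outputs = {"annotations": str(apath), "peak_matrix": str(mpath)}

        manifest["stages"][stage] = outputs

    (out / "run_config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _genesets(config: RunConfig, signature_sets: list[GeneSet] | None) -> list[GeneSet]:
    if "genesets_gmt" in config.inputs:
        return tio.read_gmt(config.inputs["genesets_gmt"])
    if signature_sets:
        return signature_sets
    raise ValueError("no genesets: provide inputs.genesets_gmt or run the signature stage")


def write_heatmap_png(frame: pd.DataFrame, path: str | Path, cmap: str = "RdBu_r") -> None:
    """Minimal heatmap rendering for quick inspection; the TSV outputs are
    the contract-bearing artifacts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, frame.shape[1] * 0.2), max(4, frame.shape[0] * 0.1)))
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
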