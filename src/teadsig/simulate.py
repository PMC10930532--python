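"""Synthetic data generators with the statistical structure the analysis
assumes, so every stage is testable without downloads.

A latent per-sample pathway-activity factor drives a planted set of
responsive genes (80 up / 52 down by default, mirroring the consensus
signature composition) on a lognormal TPM background. The generators
cover: expression matrices for two-class contrasts; a suite of partially
overlapping DE contrasts with both activation- and depletion-oriented
members; a cell-line cohort (62 lines, 17 dependent by default) whose
CRISPR fitness scores differ between activity-high and activity-low lines;
a tumor cohort where marker genes and signature genes share the latent
factor through a Gaussian copula with planted Spearman correlations; and
ChIP-seq-like peak sets preferentially placed in promoters of target
genes. Every generator is deterministic given (config, seed) and emits a
truth record for downstream assertions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneModel, GeneRecord
from .dependency import DependencyTable
from .peaks import Peak
from .signature import DETable, standin_de

logger = logging.getLogger("teadsig")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    The planted-set sizes, cohort sizes and dependency composition mirror
    the dimensions of the analysis this package re-implements (80 up / 52
    down signature genes; 62 melanoma-like cell lines with 17
    TAZ-dependent; ~300 tumors); effect sizes, noise and rates are chosen
    so the planted structure is detectable at realistic strength.
    """

    seed: int
    n_genes: int = 2000
    n_samples_per_group: int = 20
    n_up_planted: int = 80
    n_down_planted: int = 52
    effect_size: float = 2.0  # log2 units per unit of latent activity
    noise_sd: float = 0.5  # log2 units
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    planted_baseline_min: float = 2.0  # planted genes are expressed above the noise floor
    # dependency cohort
    n_cell_lines: int = 62
    n_dependent: int = 17  # TAZ(WWTR1)-dependent lines; defines the YAP/TAZ label
    n_yap_dependent: int = 2
    n_tead1_dependent: int = 9
    n_tead4_dependent: int = 1
    activity_shift: float = 2.0  # latent-activity gap between dependent and other lines (SD units)
    chronos_mean_dep: float = -1.0
    chronos_mean_indep: float = -0.1
    chronos_sd: float = 0.15
    # tumor cohort
    n_tumors: int = 300
    marker_gene: str = "CTGF"
    second_marker: str = "CYR61"
    second_marker_rho: float = 0.8
    # peaks
    n_datasets: int = 8
    promoter_rate_target: float = 0.9
    background_rate: float = 0.05
    tss_window: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_up_planted + self.n_down_planted > self.n_genes:
            raise ValueError("planted sets exceed n_genes")
        for rate in (self.promoter_rate_target, self.background_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    planted_up: list[str] = field(default_factory=list)
    planted_down: list[str] = field(default_factory=list)
    dependent_lines: dict = field(default_factory=dict)
    true_rho: dict = field(default_factory=dict)
    target_genes: list[str] = field(default_factory=list)
    support_inclusion: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_names(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    width = len(str(config.n_genes))
    names = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    up = names[: config.n_up_planted]
    down = names[config.n_up_planted : config.n_up_planted + config.n_down_planted]
    return names, up, down


def _baselines(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene log2 TPM baselines; planted genes are truncated below at
    ``planted_baseline_min`` so their fold changes survive the pseudocount
    (a DE analysis can only validate responsive genes expressed above the
    detection floor)."""
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    n_planted = config.n_up_planted + config.n_down_planted
    low = base[:n_planted] < config.planted_baseline_min
    while low.any():
        base[:n_planted][low] = rng.normal(
            config.baseline_mean, config.baseline_sd, size=int(low.sum())
        )
        low = base[:n_planted] < config.planted_baseline_min
    return base


def _expression_from_activity(
    config: SimConfig,
    activity: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
    responsive_up: set[str] | None = None,
    responsive_down: set[str] | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    names, up, down = _gene_names(config)
    if responsive_up is None:
        responsive_up = set(up)
    if responsive_down is None:
        responsive_down = set(down)
    base = _baselines(config, rng)
    sign = np.zeros(config.n_genes)
    name_pos = {g: i for i, g in enumerate(names)}
    for g in responsive_up:
        sign[name_pos[g]] = 1.0
    for g in responsive_down:
        sign[name_pos[g]] = -1.0
    log2_expr = (
        base[:, None]
        + config.effect_size * sign[:, None] * activity[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(activity)))
    )
    tpm = np.clip(np.exp2(log2_expr) - 1.0, 0.0, None)
    matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=names, columns=sample_ids),
        value_space="tpm",
        sample_meta=sample_meta,
    )
    truth = SimTruth(
        planted_up=list(up),
        planted_down=list(down),
        activity={s: float(a) for s, a in zip(sample_ids, activity)},
    )
    return matrix, truth


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-class expression matrix: 'active' samples at latent activity 1,
    'control' samples at 0, planted genes responding with ``effect_size``
    log2 units."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples_per_group
    activity = np.concatenate([np.ones(n), np.zeros(n)])
    samples = [f"ACT{i:02d}" for i in range(1, n + 1)] + [f"CTL{i:02d}" for i in range(1, n + 1)]
    meta = pd.DataFrame(
        {"phenotype_label": ["active"] * n + ["control"] * n, "lineage": "synthetic"},
        index=pd.Index(samples, name="sample_id"),
    )
    return _expression_from_activity(config, activity, samples, rng, sample_meta=meta)


def simulate_contrast_suite(
    config: SimConfig,
    n_supports: int = 3,
    support_inclusion: tuple[float, ...] = (0.8, 0.8, 0.8),
    support_orientations: tuple[str, ...] = ("activation", "depletion", "depletion"),
) -> tuple[DETable, list[DETable], SimTruth]:
    """Anchor contrast plus partially overlapping supporting contrasts.

    Every planted gene is responsive in the anchor; in each support it is
    responsive independently with that support's inclusion probability.
    Depletion-oriented supports are emitted with raw log2fc sign-flipped
    (knockdown lowers induced genes), exercising the orientation step.
    """
    if len(support_inclusion) != n_supports or len(support_orientations) != n_supports:
        raise ValueError("per-support parameter lengths must equal n_supports")
    rng = np.random.default_rng(config.seed)
    _, up, down = _gene_names(config)

    inclusion: dict[str, dict[str, list[str]]] = {}

    def one_contrast(cid: str, orientation: str, incl: float) -> DETable:
        r_up = {g for g in up if rng.random() < incl}
        r_down = {g for g in down if rng.random() < incl}
        n = config.n_samples_per_group
        activity = np.concatenate([np.ones(n), np.zeros(n)])
        samples = [f"{cid}_A{i:02d}" for i in range(n)] + [f"{cid}_B{i:02d}" for i in range(n)]
        matrix, _ = _expression_from_activity(
            config, activity, samples, rng, responsive_up=r_up, responsive_down=r_down
        )
        de = standin_de(matrix, samples[:n], samples[n:], contrast_id=cid, orientation=orientation)
        if orientation == "depletion":
            table = de.table.copy()
            table["log2fc"] = -table["log2fc"]
            de = replace(de, table=table)
        inclusion[cid] = {"up": sorted(r_up), "down": sorted(r_down)}
        return de

    anchor = one_contrast("anchor", "activation", 1.0)
    supports = [
        one_contrast(f"support{i + 1}", support_orientations[i], support_inclusion[i])
        for i in range(n_supports)
    ]
    truth = SimTruth(
        planted_up=list(up), planted_down=list(down), support_inclusion=inclusion
    )
    return anchor, supports, truth


def simulate_dependency_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, DependencyTable, SimTruth]:
    """Cell-line cohort where activity-high lines are TAZ-dependent.

    Dependent lines draw latent activity from N(activity_shift, 1) and
    Chronos(WWTR1) from N(chronos_mean_dep, chronos_sd); the remaining
    lines from N(0, 1) and N(chronos_mean_indep, chronos_sd). A subset of
    the dependent lines is additionally YAP1-, TEAD1- or TEAD4-dependent,
    echoing the composition seen in melanoma dependency screens.
    """
    if config.n_dependent >= config.n_cell_lines:
        raise ValueError("n_dependent must be < n_cell_lines")
    rng = np.random.default_rng(config.seed)
    n, k = config.n_cell_lines, config.n_dependent
    lines = [f"LINE{i:03d}" for i in range(1, n + 1)]
    dep_idx = rng.choice(n, size=k, replace=False)
    is_dep = np.zeros(n, dtype=bool)
    is_dep[dep_idx] = True
    activity = np.where(is_dep, rng.normal(config.activity_shift, 1.0, n), rng.normal(0.0, 1.0, n))
    matrix, truth = _expression_from_activity(config, activity, lines, rng)

    def chronos(dependent_mask: np.ndarray) -> np.ndarray:
        means = np.where(dependent_mask, config.chronos_mean_dep, config.chronos_mean_indep)
        return rng.normal(means, config.chronos_sd)

    dep_lines = [lines[i] for i in np.flatnonzero(is_dep)]
    sub = {
        "YAP1": set(rng.choice(dep_lines, size=min(config.n_yap_dependent, k), replace=False)),
        "TEAD1": set(rng.choice(dep_lines, size=min(config.n_tead1_dependent, k), replace=False)),
        "TEAD4": set(rng.choice(dep_lines, size=min(config.n_tead4_dependent, k), replace=False)),
    }
    scores = pd.DataFrame(index=pd.Index(lines, name="cell_line"))
    scores["WWTR1"] = chronos(is_dep)
    for gene in ("YAP1", "TEAD1", "TEAD4"):
        mask = np.array([l in sub[gene] for l in lines])
        scores[gene] = chronos(mask)
    for gene in ("TEAD2", "TEAD3"):
        scores[gene] = chronos(np.zeros(n, dtype=bool))
    lineage = pd.Series("melanoma", index=scores.index, name="lineage")
    truth.dependent_lines = {
        "WWTR1": dep_lines,
        "YAP1": sorted(sub["YAP1"]),
        "TEAD1": sorted(sub["TEAD1"]),
        "TEAD4": sorted(sub["TEAD4"]),
        "yap_taz": dep_lines,
        "tead": sorted(sub["TEAD1"] | sub["TEAD4"]),
    }
    return matrix, DependencyTable(scores, lineage), truth


def _pearson_for_spearman(rho: float) -> float:
    """Gaussian-copula Pearson correlation that yields a target Spearman
    rho (rho_S = 6/pi * arcsin(r/2), inverted)."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def simulate_tumor_cohort(
    config: SimConfig, rho_targets: dict[str, float] | None = None
) -> tuple[ExpressionMatrix, SimTruth]:
    """Tumor cohort in which signature genes share a latent factor with an
    anchor marker gene through a Gaussian copula.

    ``rho_targets`` maps gene id to the planted Spearman correlation with
    the anchor marker. By default the planted-up genes split into thirds
    at rho 0.6 / 0.3 / 0.0, background genes are uncorrelated, and a
    second marker is planted at ``second_marker_rho``. Expression is a
    monotone (lognormal) transform of the latent values, which preserves
    the planted rank correlations.
    """
    rng = np.random.default_rng(config.seed)
    names, up, down = _gene_names(config)
    if rho_targets is None:
        rho_targets = {}
        third = len(up) // 3
        for i, g in enumerate(up):
            rho_targets[g] = 0.6 if i < third else (0.3 if i < 2 * third else 0.0)
    for rho in rho_targets.values():
        if not -1.0 <= rho <= 1.0:
            raise ValueError("rho targets must be in [-1, 1]")

    n = config.n_tumors
    marker_latent = rng.standard_normal(n)
    base = _baselines(config, rng)
    all_names = [config.marker_gene, config.second_marker] + names
    values = np.empty((len(all_names), n))
    rhos = {config.marker_gene: 1.0, config.second_marker: config.second_marker_rho}
    for i, g in enumerate(all_names):
        rho = rhos.get(g, rho_targets.get(g, 0.0))
        if g == config.marker_gene:
            latent = marker_latent
        elif rho == 1.0:
            latent = marker_latent
        else:
            r = _pearson_for_spearman(rho)
            latent = r * marker_latent + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
        b = config.baseline_mean if i < 2 else base[i - 2]
        values[i] = np.clip(np.exp2(b + latent) - 1.0, 0.0, None)
    samples = [f"TUMOR{i:03d}" for i in range(1, n + 1)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=all_names, columns=samples), value_space="tpm"
    )
    truth = SimTruth(
        planted_up=list(up),
        planted_down=list(down),
        true_rho={**{g: float(r) for g, r in rho_targets.items()},
                  config.second_marker: config.second_marker_rho},
    )
    return matrix, truth


def simulate_gene_model(
    config: SimConfig, span: int = 5000, spacing: int = 20000, genes_per_chrom: int = 250
) -> GeneModel:
    """Deterministic gene model matching the synthetic gene ids: genes laid
    out along synthetic chromosomes on alternating strands, three exons
    each."""
    names, _, _ = _gene_names(config)
    records = []
    for i, g in enumerate(names):
        chrom = f"chr{i // genes_per_chrom + 1}"
        start = spacing + (i % genes_per_chrom) * spacing
        end = start + span
        strand = "+" if i % 2 == 0 else "-"
        e = span // 5
        exons = ((start, start + e), (start + 2 * e, start + 3 * e), (end - e, end))
        records.append(GeneRecord(g, chrom, strand, start, end, exons))
    return GeneModel(records)


def simulate_peaks(
    config: SimConfig, model: GeneModel, target_genes: list[str]
) -> tuple[dict[str, list[Peak]], SimTruth]:
    """Per dataset, each target gene receives a promoter peak with
    ``promoter_rate_target`` probability and each other gene with
    ``background_rate``; peaks are 200-600 bp wide, centred within the
    promoter window."""
    if len(model) == 0:
        raise ValueError("empty gene model")
    rng = np.random.default_rng(config.seed)
    targets = set(target_genes)
    datasets: dict[str, list[Peak]] = {}
    for d in range(1, config.n_datasets + 1):
        name = f"dataset{d:02d}"
        peaks: list[Peak] = []
        for rec in model:
            rate = config.promoter_rate_target if rec.gene_id in targets else config.background_rate
            if rng.random() >= rate:
                continue
            width = int(rng.integers(200, 601))
            offset = int(rng.integers(-config.tss_window // 2, config.tss_window // 2 + 1))
            center = rec.tss + offset
            start = max(0, center - width // 2)
            peaks.append(Peak(rec.chrom, start, start + width, name=f"{name}_{rec.gene_id}"))
        datasets[name] = peaks
    truth = SimTruth(target_genes=sorted(targets))
    return datasets, truth
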