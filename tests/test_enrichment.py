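"""GSEA / GSVA enrichment statistics against transparent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

from teadsig import (
    ExpressionMatrix,
    GeneSet,
    RankedList,
    choose_perm_type,
    gsea,
    gsea_es,
    gsva,
    percent_rank,
    rank_genes,
)


def brute_force_es(metric, hit, weight):
    """Literal running-sum enumeration: walk the list once, hits add
    |metric|^w / sum of hit weights, misses subtract 1/(N - Nh); return the
    signed maximum deviation."""
    n = len(metric)
    nh = sum(hit)
    # normalizer summed with numpy so both routes share one reduction order;
    # the walk itself stays a literal element-by-element loop
    nr = np.sum(np.where(hit, np.abs(np.asarray(metric)) ** weight, 0.0))
    best = 0.0
    run = 0.0
    for m, h in zip(metric, hit):
        if h:
            run += (abs(m) ** weight) / nr
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


@pytest.fixture
def eight_gene_list():
    metrics = np.array([2.3, 1.7, 1.1, 0.6, 0.2, -0.4, -1.0, -2.1])
    genes = [f"R{i}" for i in range(1, 9)]
    return RankedList(genes, metrics)


class TestEsOracle:
    def test_all_genesets_up_to_size_three(self, eight_gene_list):
        """ES matches the exhaustive brute-force running sum for every
        geneset of size 1-3 over an 8-gene list (all 92 sets), exactly."""
        genes = eight_gene_list.genes
        n_checked = 0
        for k in (1, 2, 3):
            for combo in itertools.combinations(genes, k):
                gs = GeneSet("X", "", combo)
                es, _, _ = gsea_es(eight_gene_list, gs)
                hit = [g in combo for g in genes]
                assert es == pytest.approx(
                    brute_force_es(eight_gene_list.metric, hit, 1.0), abs=0
                ), combo
                n_checked += 1
        assert n_checked == 92

    def test_full_geneset_gives_es_one(self, eight_gene_list):
        gs = GeneSet("ALL", "", tuple(eight_gene_list.genes))
        es, _, leading = gsea_es(eight_gene_list, gs)
        assert es == pytest.approx(1.0)
        assert leading == list(eight_gene_list.genes)

    def test_reversal_negates_es_unweighted(self, eight_gene_list):
        """With weight 0 the walk is symmetric: reversing the list negates
        the ES of any proper subset."""
        gs = GeneSet("S", "", ("R1", "R2", "R5"))
        es_fwd, _, _ = gsea_es(eight_gene_list, gs, weight=0)
        rev = RankedList(
            list(reversed(eight_gene_list.genes)), eight_gene_list.metric[::-1]
        )
        es_rev, _, _ = gsea_es(rev, gs, weight=0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_absent_geneset_rejected(self, eight_gene_list):
        with pytest.raises(ValueError, match="not represented"):
            gsea_es(eight_gene_list, GeneSet("X", "", ("NOPE",)))

    def test_es_bounded(self, rng, eight_gene_list):
        for _ in range(50):
            k = int(rng.integers(1, 8))
            combo = tuple(rng.choice(eight_gene_list.genes, size=k, replace=False))
            es, _, _ = gsea_es(eight_gene_list, GeneSet("X", "", combo))
            assert -1.0 <= es <= 1.0

    def test_leading_edge_subset_of_hits(self, eight_gene_list):
        gs = GeneSet("S", "", ("R2", "R7", "R8"))
        es, _, leading = gsea_es(eight_gene_list, gs)
        assert set(leading) <= {"R2", "R7", "R8"}


class TestRankGenes:
    def test_signal_to_noise_closed_form(self):
        a = np.array([[4.0, 5.0, 6.0]])
        b = np.array([[1.0, 1.5, 2.0]])
        vals = np.concatenate([a, b], axis=1)
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=["G"], columns=list("abcdef")), "log2p1"
        )
        ranked = rank_genes(m, list("abc"), list("def"))
        sd_a = max(np.std(a, ddof=1), 0.2 * 5.0)
        sd_b = max(np.std(b, ddof=1), 0.2 * 1.5)
        assert ranked.metric[0] == pytest.approx((5.0 - 1.5) / (sd_a + sd_b))

    def test_equal_means_give_zero(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["G"], columns=list("abcd")),
            "log2p1",
        )
        assert rank_genes(m, ["a", "b"], ["c", "d"]).metric[0] == 0.0

    def test_constant_zero_gene_uses_epsilon_floor(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0] * 4], index=["G"], columns=list("abcd")), "log2p1"
        )
        assert rank_genes(m, ["a", "b"], ["c", "d"]).metric[0] == 0.0

    def test_ties_broken_by_symbol(self):
        vals = np.zeros((3, 4))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=["B", "A", "C"], columns=list("abcd")), "log2p1"
        )
        assert rank_genes(m, ["a", "b"], ["c", "d"]).genes == ["A", "B", "C"]


class TestPermutationRule:
    @pytest.mark.parametrize("na, nb, expected", [(5, 5, "geneset"), (8, 8, "phenotype"),
                                                  (7, 20, "geneset"), (9, 8, "phenotype")])
    def test_group_size_rule(self, na, nb, expected):
        assert choose_perm_type(na, nb) == expected

    def test_gsea_reports_selected_mode_and_is_reproducible(self, rng):
        genes = [f"G{i:03d}" for i in range(80)]
        vals = rng.normal(size=(80, 10))
        m = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=[f"S{i}" for i in range(10)]),
                             "log2p1")
        sets = [GeneSet(f"SET{j}", "", tuple(rng.choice(genes, 8, replace=False))) for j in range(3)]
        a, b = [f"S{i}" for i in range(5)], [f"S{i}" for i in range(5, 10)]
        r1 = gsea(m, a, b, sets, nperm=50, seed=11)
        r2 = gsea(m, a, b, sets, nperm=50, seed=11)
        assert all(x.perm_type == "geneset" for x in r1)
        assert [(x.es, x.nes, x.nominal_p, x.fdr_q) for x in r1] == [
            (x.es, x.nes, x.nominal_p, x.fdr_q) for x in r2
        ]

    def test_nperm_floor(self, small_matrix, toy_geneset):
        with pytest.raises(ValueError):
            gsea(small_matrix, small_matrix.sample_ids[:4], small_matrix.sample_ids[4:],
                 [toy_geneset], nperm=5)


class TestPercentRank:
    def test_formula_and_bins(self):
        genes = [f"G{i:04d}" for i in range(1, 201)]
        ranked = RankedList(genes, np.linspace(5, -5, 200))
        out = percent_rank(ranked, [genes[0], genes[99], "ABSENT"])
        assert out.loc[genes[0], "pct"] == pytest.approx(0.5)
        assert out.loc[genes[0], "bin"] == "top"
        assert out.loc[genes[99], "pct"] == pytest.approx(50.0)
        assert out.loc[genes[99], "bin"] == "mid"
        assert out.loc["ABSENT", "bin"] == "absent"
        assert np.isnan(out.loc["ABSENT", "pct"])

    def test_bins_partition_represented_genes(self):
        genes = [f"G{i:03d}" for i in range(100)]
        ranked = RankedList(genes, np.arange(100, 0, -1, dtype=float))
        out = percent_rank(ranked, genes)
        assert set(out["bin"]) <= {"top", "mid", "bottom"}
        assert (out["bin"] == "top").sum() + (out["bin"] == "mid").sum() + (
            out["bin"] == "bottom"
        ).sum() == 100


def gsva_oracle(values, gene_names, member_sets, tau=1.0, mx_diff=True):
    """Transparent two-pass reimplementation: explicit kernel CDF table,
    per-sample ranks, then the symmetric-rank random walk, all in loops."""
    g, n = values.shape
    scores = {}
    # pass 1: Gaussian kernel CDF estimates, bandwidth sd/4
    z = np.zeros_like(values)
    for i in range(g):
        h = max(np.std(values[i], ddof=1) / 4.0, 1e-8)
        for j in range(n):
            z[i, j] = np.mean([ndtr((values[i, j] - values[i, k]) / h) for k in range(n)])
    # pass 2: per-sample walk
    for name, members in member_sets.items():
        out = np.zeros(n)
        for j in range(n):
            order = sorted(range(g), key=lambda i: (-z[i, j], gene_names[i]))
            ranks = {order[pos]: pos + 1 for pos in range(g)}
            stat = {i: abs(g / 2.0 - ranks[i]) ** tau for i in range(g)}
            nr = sum(stat[i] for i in range(g) if gene_names[i] in members)
            nh = sum(1 for i in range(g) if gene_names[i] in members)
            run, top, bottom = 0.0, 0.0, 0.0
            for i in order:
                if gene_names[i] in members:
                    run += stat[i] / nr
                else:
                    run -= 1.0 / (g - nh)
                top, bottom = max(top, run), min(bottom, run)
            out[j] = top + bottom if mx_diff else (top if top > -bottom else bottom)
        scores[name] = out
    return scores


class TestGsva:
    def _matrix(self, rng, g=6, n=4):
        genes = [f"G{i}" for i in range(g)]
        vals = rng.normal(5, 2, size=(g, n))
        return ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"S{i}" for i in range(n)]), "log2p1"
        )

    def test_matches_two_pass_oracle(self, rng):
        m = self._matrix(rng)
        members = {"SET": {"G0", "G2", "G4"}}
        ours = gsva(m, [GeneSet("SET", "", ("G0", "G2", "G4"))])
        oracle = gsva_oracle(m.values.to_numpy(), m.gene_ids, members)
        np.testing.assert_allclose(
            ours.scores.loc["SET"].to_numpy(), oracle["SET"], atol=1e-9
        )

    def test_affine_transform_of_one_gene_is_invariant(self, rng):
        m = self._matrix(rng, g=10, n=6)
        s1 = gsva(m, [GeneSet("S", "", ("G1", "G3", "G5"))]).scores
        vals = m.values.copy()
        vals.loc["G3"] = 7.0 + 3.5 * vals.loc["G3"]  # strictly increasing
        m2 = ExpressionMatrix(vals, "log2p1")
        s2 = gsva(m2, [GeneSet("S", "", ("G1", "G3", "G5"))]).scores
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_ecdf_kernel_invariant_under_any_monotone_transform(self, rng):
        m = self._matrix(rng, g=10, n=6)
        gs = [GeneSet("S", "", ("G1", "G3", "G5"))]
        s1 = gsva(m, gs, kcdf="ecdf").scores
        vals = m.values.copy()
        vals.loc["G3"] = np.exp(vals.loc["G3"] / 2.0)  # nonlinear, monotone
        s2 = gsva(ExpressionMatrix(vals, "log2p1"), gs, kcdf="ecdf").scores
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_sample_permutation_equivariance(self, rng):
        m = self._matrix(rng, g=8, n=5)
        gs = [GeneSet("S", "", ("G0", "G4"))]
        s1 = gsva(m, gs).scores
        perm = ["S3", "S0", "S4", "S1", "S2"]
        s2 = gsva(m.subset_samples(perm), gs).scores
        np.testing.assert_allclose(s1[perm].to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_planted_set_and_complement_move_oppositely(self):
        """Activity-high samples score higher for a planted-up set and lower
        for its complement (two-block design, n=30 per block)."""
        rng = np.random.default_rng(5)
        g, n = 60, 60
        genes = [f"G{i:02d}" for i in range(g)]
        activity = np.concatenate([np.ones(30), np.zeros(30)])
        up = set(genes[:15])
        vals = rng.normal(4, 1, size=(g, n))
        for i, gene in enumerate(genes):
            if gene in up:
                vals[i] += 2.0 * activity
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"S{i}" for i in range(n)]), "log2p1"
        )
        sets = [GeneSet("UP", "", tuple(sorted(up))),
                GeneSet("REST", "", tuple(sorted(set(genes) - up)))]
        scores = gsva(m, sets).scores
        hi, lo = scores.columns[:30], scores.columns[30:]
        p_up = stats.mannwhitneyu(scores.loc["UP", hi], scores.loc["UP", lo],
                                  alternative="greater").pvalue
        p_rest = stats.mannwhitneyu(scores.loc["REST", hi], scores.loc["REST", lo],
                                    alternative="less").pvalue
        assert p_up < 0.01 and p_rest < 0.01

    def test_requires_three_samples(self, rng):
        m = self._matrix(rng, g=4, n=2)
        with pytest.raises(ValueError):
            gsva(m, [GeneSet("S", "", ("G0",))])
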