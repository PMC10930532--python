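"""Marker-anchored tumor-cohort correlation analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teadsig import (
    ExpressionMatrix,
    assign_groups,
    group_compare,
    log2p1,
    similarity_matrix,
    spearman_vs_marker,
    strong_correlation_venn,
)
from teadsig.cohort import CorrelationReport, correlation_bin
from teadsig.simulate import SimConfig, simulate_tumor_cohort


def _matrix(rows: dict, space="log2p1"):
    df = pd.DataFrame(rows).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, space)


class TestAssignGroups:
    def test_inclusive_boundaries(self):
        # marker values engineered to mean 0, SD 1 exactly is fiddly; use a
        # direct construction and check against the computed thresholds
        vals = np.array([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0])
        m = _matrix({"M": vals})
        g = assign_groups(m, "M")
        hi_cut = g.mean + g.sd
        assert all(vals[i] >= hi_cut for i, s in enumerate(g.groups) if s == "high")
        assert all(vals[i] <= g.mean - g.sd for i, s in enumerate(g.groups) if s == "low")
        assert set(g.groups) == {"high", "low", "neither"}

    def test_exact_one_sd_is_grouped(self):
        vals = np.array([-1.0, 0.0, 0.0, 0.0, 0.0, 1.0])
        m = _matrix({"M": vals})
        g = assign_groups(m, "M")
        sd = np.std(vals, ddof=1)
        # the extreme samples sit beyond mean +/- sd, check inclusivity via k
        g2 = assign_groups(m, "M", k=1.0 / sd)  # thresholds exactly +/-1
        assert g2.groups.iloc[0] == "low" and g2.groups.iloc[-1] == "high"

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(99)
        vals = rng.standard_normal(10000)
        g = assign_groups(_matrix({"M": vals}), "M")
        assert (np.array(g.groups) == "high").mean() == pytest.approx(0.1587, abs=0.01)
        assert (np.array(g.groups) == "low").mean() == pytest.approx(0.1587, abs=0.01)

    def test_degenerate_marker_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            assign_groups(_matrix({"M": np.ones(6)}), "M")


class TestGroupCompare:
    def _grouped(self, rng, shift):
        n = 60
        marker = np.concatenate([rng.normal(3, 0.2, 20), rng.normal(6, 0.2, 20),
                                 rng.normal(4.5, 0.2, 20)])
        gene = rng.normal(5, 1, n)
        gene[20:40] += shift  # tracks the marker-high block
        m = _matrix({"M": marker, "G1": gene})
        return m, assign_groups(m, "M")

    def test_planted_shift_detected(self, rng):
        m, grouping = self._grouped(rng, shift=2.0)
        out = group_compare(m, grouping, ["G1"])
        assert out.loc["G1", "fdr"] < 0.05
        assert out.loc["G1", "median_high"] > out.loc["G1", "median_low"]

    def test_null_gene_not_significant(self, rng):
        m, grouping = self._grouped(rng, shift=0.0)
        assert group_compare(m, grouping, ["G1"]).loc["G1", "p"] > 0.05

    def test_label_swap_symmetry(self, rng):
        m, grouping = self._grouped(rng, shift=1.0)
        swapped = grouping
        swapped.groups = grouping.groups.map({"high": "low", "low": "high"}).fillna("neither")
        p1 = group_compare(m, grouping, ["G1"])["p"]
        m2, g2 = self._grouped(np.random.default_rng(20240220), shift=1.0)
        pd.testing.assert_series_equal(p1, group_compare(m2, swapped, ["G1"])["p"])

    def test_small_groups_rejected(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        m = _matrix({"M": vals, "G1": vals})
        with pytest.raises(ValueError):
            group_compare(m, assign_groups(m, "M"), ["G1"])


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        m = _matrix({"M": x, "UP": np.exp(x), "DN": -(x**3)})
        rep = spearman_vs_marker(m, "M", ["UP", "DN"], nperm=50, seed=0)
        assert rep.table.loc["UP", "spearman_r"] == pytest.approx(1.0)
        assert rep.table.loc["DN", "spearman_r"] == pytest.approx(-1.0)

    def test_constant_gene_flagged(self):
        m = _matrix({"M": np.arange(6.0), "C": np.ones(6)})
        rep = spearman_vs_marker(m, "M", ["C"], nperm=50, seed=0)
        row = rep.table.loc["C"]
        assert row["flagged"] and row["bin"] == "weak" and row["permutation_p"] == 1.0

    def test_matches_scipy_spearman(self, rng):
        vals = rng.normal(size=(6, 40))
        genes = {f"G{i}": vals[i] for i in range(5)}
        genes["M"] = vals[5]
        m = _matrix(genes)
        rep = spearman_vs_marker(m, "M", [f"G{i}" for i in range(5)], nperm=20, seed=0)
        for i in range(5):
            expected = stats.spearmanr(vals[i], vals[5]).statistic
            assert rep.table.loc[f"G{i}", "spearman_r"] == pytest.approx(expected, abs=1e-12)

    def test_null_calibration(self):
        """Independent genes show ~5% of permutation p-values below 0.05."""
        rng = np.random.default_rng(17)
        n, n_genes = 50, 200
        rows = {f"G{i:03d}": rng.normal(size=n) for i in range(n_genes)}
        rows["M"] = rng.normal(size=n)
        m = _matrix(rows)
        rep = spearman_vs_marker(m, "M", [f"G{i:03d}" for i in range(n_genes)],
                                 nperm=400, seed=3)
        frac = (rep.table["permutation_p"] < 0.05).mean()
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) <= ci

    def test_monotone_transform_invariance(self, rng):
        base = rng.normal(size=(3, 30))
        m1 = _matrix({"M": base[0], "A": base[1], "B": base[2]})
        m2 = _matrix({"M": base[0], "A": np.exp(base[1]), "B": base[2] ** 3})
        r1 = spearman_vs_marker(m1, "M", ["A", "B"], nperm=10, seed=1).table["spearman_r"]
        r2 = spearman_vs_marker(m2, "M", ["A", "B"], nperm=10, seed=1).table["spearman_r"]
        pd.testing.assert_series_equal(r1, r2)

    def test_planted_rho_recovered(self):
        cfg = SimConfig(seed=42, n_genes=300, n_tumors=300)
        matrix, truth = simulate_tumor_cohort(cfg)
        m = log2p1(matrix)
        planted = {g: r for g, r in truth.true_rho.items() if g in set(m.gene_ids)}
        probe = {0.0: None, 0.3: None, 0.6: None}
        for g, r in planted.items():
            if r in probe and probe[r] is None:
                probe[r] = g
        rep = spearman_vs_marker(m, cfg.marker_gene, list(planted), nperm=50, seed=5)
        for rho, g in probe.items():
            assert rep.table.loc[g, "spearman_r"] == pytest.approx(rho, abs=0.15)


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal_and_sorted(self, rng):
        rows = {f"G{i}": rng.normal(size=25) for i in range(6)}
        rows["M"] = rng.normal(size=25)
        m = _matrix(rows)
        sim = similarity_matrix(m, [f"G{i}" for i in range(6)], "M")
        mat = sim.matrix
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        anchor_col = mat["M"]
        assert list(anchor_col.index) == list(anchor_col.sort_values(ascending=False, kind="stable").index)

    def test_entries_match_rank_then_pearson_oracle(self, rng):
        rows = {f"G{i}": rng.normal(size=15) for i in range(5)}
        m = _matrix(rows)
        sim = similarity_matrix(m, [f"G{i}" for i in range(5)], "G0")
        for a in sim.matrix.index:
            for b in sim.matrix.columns:
                ra = stats.rankdata(m.values.loc[a])
                rb = stats.rankdata(m.values.loc[b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert sim.matrix.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_anchor_row_matches_marker_report(self, rng):
        rows = {f"G{i}": rng.normal(size=30) for i in range(8)}
        rows["M"] = rng.normal(size=30)
        m = _matrix(rows)
        genes = [f"G{i}" for i in range(8)]
        sim = similarity_matrix(m, genes, "M")
        rep = spearman_vs_marker(m, "M", genes, nperm=10, seed=0)
        for g in genes:
            assert sim.matrix.loc["M", g] == pytest.approx(
                rep.table.loc[g, "spearman_r"], abs=1e-12
            )


class TestBinsAndVenn:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.5, "strong"), (0.4, "strong"), (0.39, "moderate"), (0.3, "moderate"),
         (0.29, "weak"), (-0.5, "weak"), (np.nan, "weak")],
    )
    def test_bin_boundaries(self, r, expected):
        assert correlation_bin(r) == expected

    def _report(self, marker, rs):
        table = pd.DataFrame(
            {"spearman_r": list(rs.values()), "permutation_p": 0.01,
             "bin": [correlation_bin(r) for r in rs.values()], "flagged": False},
            index=list(rs),
        )
        return CorrelationReport(marker, table)

    def test_venn_counts(self):
        a = self._report("CTGF", {"G1": 0.5, "G2": 0.2, "G3": 0.4})
        b = self._report("CYR61", {"G1": 0.2, "G2": 0.45, "G3": 0.4})
        assert strong_correlation_venn(a, b) == {"only_a": 1, "only_b": 1, "both": 1}

    def test_mismatched_universe_rejected(self):
        a = self._report("CTGF", {"G1": 0.5})
        b = self._report("CYR61", {"G2": 0.5})
        with pytest.raises(ValueError):
            strong_correlation_venn(a, b)

    def test_counts_match_brute_force(self, rng):
        rs_a = {f"G{i}": float(rng.uniform(-1, 1)) for i in range(50)}
        rs_b = {f"G{i}": float(rng.uniform(-1, 1)) for i in range(50)}
        out = strong_correlation_venn(self._report("A", rs_a), self._report("B", rs_b))
        sa = {g for g, r in rs_a.items() if r >= 0.4}
        sb = {g for g, r in rs_b.items() if r >= 0.4}
        assert out == {"only_a": len(sa - sb), "only_b": len(sb - sa), "both": len(sa & sb)}
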