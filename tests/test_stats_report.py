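"""PCA of frequency tables, nonparametric group tests, comparison tables,
report bundles."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import cytocomm as cc

from conftest import mann_whitney_enumeration


def _freq_fixture(shift_pop="P1", shift=10.0, n=12, seed=0):
    r = np.random.default_rng(seed)
    pops = ["P1", "P2", "P3", "P4"]
    base = r.uniform(10, 20, size=(n, 4))
    df = pd.DataFrame(base, columns=pops,
                      index=[f"s{i}" for i in range(n)])
    df.loc[df.index[n // 2:], shift_pop] += shift
    return df


class TestPCA:
    def test_shifted_population_is_top_pc1_contributor(self):
        # compositional cohort: second group enriched in P3 (tight), other
        # populations carry independent sample-to-sample noise
        r = np.random.default_rng(0)
        rows = []
        for i in range(12):
            base = np.array([30.0, 25.0, 10.0, 35.0]) + r.normal(
                0, [5.0, 5.0, 0.7, 5.0]
            )
            if i >= 6:
                base[2] += 25.0
            rows.append(100 * base / base.sum())
        freq = pd.DataFrame(rows, columns=["P1", "P2", "P3", "P4"],
                            index=[f"s{i}" for i in range(12)])
        res = cc.pca_frequencies(freq)
        pc1_contrib = (res.loadings["PC1"] ** 2).sort_values(ascending=False)
        assert pc1_contrib.index[0] == "P3"

    def test_loadings_orthonormal(self):
        res = cc.pca_frequencies(_freq_fixture())
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_full_reconstruction(self):
        freq = _freq_fixture(seed=3)
        res = cc.pca_frequencies(freq)
        Z = (freq - freq.mean()) / freq.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-10)

    def test_explained_variance_non_increasing_and_sums_to_one(self):
        res = cc.pca_frequencies(_freq_fixture(seed=5))
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() == pytest.approx(1.0)

    def test_missing_values_refused(self):
        freq = _freq_fixture()
        freq.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cc.pca_frequencies(freq)

    def test_constant_population_dropped_with_warning(self):
        freq = _freq_fixture()
        freq["P4"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = cc.pca_frequencies(freq)
        assert "P4" in res.dropped
        assert "P4" not in res.loadings.index


class TestMannWhitney:
    def test_fully_separated_toy(self):
        u, p = cc.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_groups_give_p_one(self):
        _, p = cc.mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    @pytest.mark.parametrize("na", [1, 2, 3, 4])
    def test_exact_branch_matches_enumeration_oracle(self, na, rng):
        for rep in range(10):
            pooled = rng.normal(size=8)
            if rep % 2:
                pooled = np.round(pooled)  # force ties
            a, b = pooled[:na], pooled[na:]
            _, p = cc.mann_whitney(a, b)
            assert p == pytest.approx(mann_whitney_enumeration(a, b))

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(6) + 0.5
        _, p = cc.mann_whitney(a, b)
        p_scipy = mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
        assert p == pytest.approx(p_scipy)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            cc.mann_whitney([], [1.0])

    def test_invariant_to_sample_order(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(5)
        _, p1 = cc.mann_whitney(a, b)
        _, p2 = cc.mann_whitney(a[::-1], b[::-1])
        assert p1 == p2


class TestKruskalWallisDunn:
    def test_identical_groups(self):
        g = {"a": np.ones(4), "b": np.ones(4), "c": np.ones(4)}
        res = cc.kruskal_wallis_dunn(g)
        assert res.h == pytest.approx(0.0, abs=1e-12)
        assert (res.dunn["p"] > 0.99).all()

    def test_shifted_group_has_smallest_pairwise_p(self, rng):
        g = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0, 1, 8),
            "c": rng.normal(6, 1, 8),  # clearly shifted
        }
        res = cc.kruskal_wallis_dunn(g)
        dunn = res.dunn.sort_values("p")
        involved = set(dunn.iloc[0][["group_a", "group_b"]]) | set(
            dunn.iloc[1][["group_a", "group_b"]]
        )
        assert "c" in set(dunn.iloc[0][["group_a", "group_b"]])
        assert "c" in set(dunn.iloc[1][["group_a", "group_b"]])
        assert dunn.iloc[2]["p"] > dunn.iloc[1]["p"]

    def test_hand_computed_h_on_3x3_toy(self):
        # groups (1,2,3), (4,5,6), (7,8,9): ranks are 1..9 exactly;
        # H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 with rbar = 5:
        # rank means 2, 5, 8 -> H = 12/90 * 3*(9+0+9) = 7.2
        res = cc.kruskal_wallis_dunn(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        )
        assert res.h == pytest.approx(7.2)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError, match="3 groups"):
            cc.kruskal_wallis_dunn({"a": [1, 2], "b": [3, 4]})


class TestComparePopulations:
    @staticmethod
    def _sheet(freq, split=4):
        return pd.DataFrame(
            {
                "sample_id": freq.index,
                "group": ["LN"] * split + ["DLBCL"] * (len(freq) - split),
                "path": "",
            }
        )

    def test_enriched_population_flagged(self, small_cohort):
        freq = cc.mc_frequencies(
            small_cohort.truth["metacluster"], small_cohort.truth["sample_id"]
        )
        comp = cc.compare_populations(
            freq, small_cohort.sample_sheet, design="two-group"
        )
        row = comp[comp["population"] == "mc09_follicular"].iloc[0]
        assert row["p"] < 0.05
        assert row["tier"] in {"*", "**", "***"}
        assert len(comp) == freq.shape[1]

    def test_permuted_labels_significant_at_nominal_rate(self, rng):
        n_rep, n_pops = 100, 6
        count = 0
        for rep in range(n_rep):
            freq = pd.DataFrame(
                rng.uniform(5, 25, size=(9, n_pops)),
                columns=[f"P{j}" for j in range(n_pops)],
                index=[f"s{i}" for i in range(9)],
            )
            comp = cc.compare_populations(freq, self._sheet(freq), "two-group")
            count += int((comp["p"] < 0.05).sum())
        rate = count / (n_rep * n_pops)
        assert rate <= 0.09  # near-nominal; exact test is discrete

    def test_unknown_design_raises(self, small_cohort):
        freq = cc.mc_frequencies(
            small_cohort.truth["metacluster"], small_cohort.truth["sample_id"]
        )
        with pytest.raises(ValueError, match="design"):
            cc.compare_populations(freq, small_cohort.sample_sheet, "anova")

    def test_tiers_are_pure_function_of_adjusted_p(self):
        assert cc.significance_tier(0.2) == "ns"
        assert cc.significance_tier(0.04) == "*"
        assert cc.significance_tier(0.009) == "**"
        assert cc.significance_tier(0.0009) == "***"


class TestBuildReport:
    def test_manifest_lists_every_table_and_marks_missing(self, tmp_path):
        tables = {
            "comparisons": pd.DataFrame({"a": [1, 2]}),
            "frequencies": pd.DataFrame({"b": [3.0]}),
        }
        manifest = cc.build_report(
            tables, tmp_path, params={"k": 11}, seed=7,
            expected_stages=["comparisons", "frequencies", "lr_screen"],
        )
        assert manifest["tables"]["comparisons"]["present"]
        assert not manifest["tables"]["lr_screen"]["present"]
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert set(on_disk["tables"]) == {"comparisons", "frequencies",
                                          "lr_screen"}
        assert (tmp_path / "comparisons.csv").exists()
        assert (tmp_path / "run.log").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        tables = {"t": pd.DataFrame({"x": [1.5, 2.5], "y": ["a", "b"]})}
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        cc.build_report(tables, d1, seed=3)
        cc.build_report(tables, d2, seed=3)
        for name in ("t.csv", "manifest.json", "run.log"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
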