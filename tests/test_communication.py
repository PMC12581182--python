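"""Signed distance correlation, permutation p-values, profile building and
ligand-receptor / frequency screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cytocomm as cc
from cytocomm.synthetic import CohortSpec, LRCouplingSpec, MetaclusterSpec

from conftest import dcor_bruteforce


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(30)
        assert cc.distance_correlation(x, x) == pytest.approx(1.0)

    def test_affine_dependence_gives_one(self, rng):
        x = rng.standard_normal(25)
        assert cc.distance_correlation(x, 3 * x - 2) == pytest.approx(1.0)

    def test_frozen_bruteforce_value(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = x**2
        # frozen from the explicit-loop double-centering oracle
        assert cc.distance_correlation(x, y) == pytest.approx(
            0.9869160440537483, abs=1e-12
        )

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert abs(
                cc.distance_correlation(x, y) - dcor_bruteforce(x, y)
            ) < 1e-12

    def test_blocked_path_matches_direct(self, rng):
        x = rng.standard_normal(500)
        y = 0.5 * x + rng.standard_normal(500)
        direct = cc.distance_correlation(x, y)
        blocked = cc.distance_correlation(x, y, block_threshold=120)
        assert blocked == pytest.approx(direct, abs=1e-12)

    def test_constant_argument_gives_zero(self, rng):
        x = rng.standard_normal(10)
        assert cc.distance_correlation(x, np.full(10, 3.0)) == 0.0

    @given(
        st.floats(min_value=0.1, max_value=50),
        st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_positive_affine_maps(self, a, b):
        r = np.random.default_rng(99)
        x = r.standard_normal(15)
        y = r.standard_normal(15) + 0.5 * x
        base = cc.distance_correlation(x, y)
        assert cc.distance_correlation(a * x + b, y) == pytest.approx(
            base, abs=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least"):
            cc.distance_correlation([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="finite"):
            cc.distance_correlation([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestSignedDcor:
    def test_negation_gives_minus_one(self, rng):
        x = rng.standard_normal(20)
        res = cc.signed_dcor(x, -x)
        assert res.value == pytest.approx(-1.0)
        assert not res.zero_sign

    def test_symmetric_quadratic_has_exact_zero_pearson_and_flag(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x**2
        res = cc.signed_dcor(x, y)
        assert res.pearson == 0.0
        assert res.zero_sign
        assert res.value > 0  # sign defaults to +1, magnitude kept

    def test_sign_antisymmetry_when_pearson_nonzero(self, rng):
        x = rng.standard_normal(18)
        y = 0.7 * x + 0.3 * rng.standard_normal(18)
        assert cc.signed_dcor(x, -y).value == pytest.approx(
            -cc.signed_dcor(x, y).value
        )

    def test_magnitude_equals_dcor(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        res = cc.signed_dcor(x, y)
        assert abs(res.value) == pytest.approx(res.dcor)


class TestDcorPValue:
    def test_exact_p_granularity_n4(self):
        # generic (non-arithmetic) values: only the identity permutation
        # attains the observed statistic
        x = np.array([1.0, 2.0, 4.0, 8.0])
        p = cc.dcor_pvalue(x, x.copy(), method="exact")
        assert p == pytest.approx(1 / 24)
        y = np.array([3.0, 1.0, 9.0, 2.0])
        p2 = cc.dcor_pvalue(x, y, method="exact")
        assert (24 * p2) == pytest.approx(round(24 * p2))  # multiple of 1/24

    def test_identity_pair_attains_minimum_p(self, rng):
        x = np.sort(rng.standard_normal(6))
        p_self = cc.dcor_pvalue(x, x.copy(), method="exact")
        y = rng.standard_normal(6)
        assert p_self <= cc.dcor_pvalue(x, y, method="exact")

    def test_exact_null_p_uniform_on_support(self):
        # for fixed x and all y-orderings, #{p <= t} / n! <= t at each
        # achievable level (validity of the permutation p-value)
        from itertools import permutations

        x = np.array([0.3, 1.9, 2.2, 4.1])
        base_y = np.array([1.0, 3.5, 0.2, 2.8])
        ps = [
            cc.dcor_pvalue(x, base_y[list(perm)], method="exact")
            for perm in permutations(range(4))
        ]
        ps = np.array(ps)
        for t in np.unique(ps):
            assert (ps <= t).mean() <= t + 1e-12

    def test_monte_carlo_p_bounds_and_determinism(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        p1 = cc.dcor_pvalue(x, y, method="monte-carlo", n_perm=199, seed=4)
        p2 = cc.dcor_pvalue(x, y, method="monte-carlo", n_perm=199, seed=4)
        assert p1 == p2
        assert 1 / 200 <= p1 <= 1.0

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_rep = 400
        for i in range(n_rep):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            p = cc.dcor_pvalue(x, y, method="monte-carlo", n_perm=199, seed=i)
            rejections += p <= 0.05
        # 95% binomial band around 0.05 at n=400: [0.029, 0.071]
        assert 0.029 <= rejections / n_rep <= 0.071

    def test_invalid_method_raises(self, rng):
        with pytest.raises(ValueError, match="method"):
            cc.dcor_pvalue(rng.random(5), rng.random(5), method="bootstrap")


class TestBHAdjust:
    def test_hand_arithmetic_example(self):
        np.testing.assert_allclose(
            cc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert cc.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.uniform(0.001, 1.0, 30)
        adj = cc.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        # order-preserving: ranks of adjusted match ranks of raw
        assert (np.argsort(np.argsort(p)) <= np.argsort(np.argsort(adj)) + 29).all()
        sort_idx = np.argsort(p)
        assert (np.diff(adj[sort_idx]) >= -1e-15).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cc.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            cc.bh_adjust([1.5])


class TestMedianProfile:
    def _events(self, values, labels, sid="s1"):
        em = cc.EventMatrix(sid, ["M", "Time"],
                            np.column_stack([values, np.arange(len(values))]))
        return {sid: em}, {sid: np.asarray(labels)}

    def test_single_cell_population_is_that_cell(self):
        ev, asg = self._events([7.0, 1.0, 1.0], ["solo", "rest", "rest"])
        prof = cc.median_profile(ev, asg, markers=["M"])
        row = prof[(prof["population"] == "solo") & (prof["marker"] == "M")]
        assert row["mfi"].iloc[0] == 7.0
        assert row["n_cells"].iloc[0] == 1

    def test_odd_count_median(self):
        ev, asg = self._events([1.0, 5.0, 9.0], ["p", "p", "p"])
        prof = cc.median_profile(ev, asg, markers=["M"])
        assert prof["mfi"].iloc[0] == 5.0

    def test_invariant_to_event_order(self, rng):
        vals = rng.random(60)
        labs = rng.choice(["a", "b"], 60)
        ev, asg = self._events(vals, labs)
        perm = rng.permutation(60)
        ev2, asg2 = self._events(vals[perm], labs[perm])
        p1 = cc.median_profile(ev, asg, markers=["M"]).sort_values("population")
        p2 = cc.median_profile(ev2, asg2, markers=["M"]).sort_values("population")
        np.testing.assert_allclose(p1["mfi"].to_numpy(), p2["mfi"].to_numpy())

    def test_small_populations_become_missing_entries(self):
        ev, asg = self._events([1.0, 2.0, 3.0, 4.0], ["tiny", "big", "big", "big"])
        prof = cc.median_profile(ev, asg, markers=["M"], min_cells=2)
        assert "tiny" not in set(prof["population"])


def _coupled_cohort(seed, n_samples=20, beta=0.4, link="linear"):
    mcs = [
        MetaclusterSpec("tcell", {"A": 0.5, "B": 0.5},
                        {"ICOS": 0.5, "PD1": 0.45}),
        MetaclusterSpec("bcell", {"A": 0.5, "B": 0.5},
                        {"ICOSL": 0.5, "PDL2": 0.45}),
    ]
    half = n_samples // 2
    spec = CohortSpec(
        groups=[("A", half), ("B", n_samples - half)],
        cells_per_sample=250,
        markers=["ICOS", "ICOSL", "PD1", "PDL2"],
        metaclusters=mcs,
        lr_couplings=[
            LRCouplingSpec("tcell", "ICOS", "bcell", "ICOSL",
                           link=link, beta=beta, noise_sd=0.02)
        ],
        seed=seed,
    )
    return cc.simulate_cohort(spec)


class TestScreens:
    def test_injected_linear_coupling_ranked_first_and_significant(self):
        cohort = _coupled_cohort(seed=2)
        truth = {
            sid: em.labels["metacluster"].to_numpy()
            for sid, em in cohort.events.items()
        }
        profiles = cc.median_profile(cohort.events, truth)
        cat = cc.default_lr_catalogue()
        table = cc.lr_screen(profiles, cat, ["tcell"], ["bcell"],
                             n_perm=999, seed=8)
        top = table.iloc[0]
        assert {top["ligand"], top["receptor"]} == {"ICOS", "ICOSL"}
        assert top["significant"]
        assert top["p"] < 0.05 < table.iloc[-1]["p"] + 1  # full table kept

    def test_catalogue_pair_with_missing_marker_skipped_with_warning(self):
        cohort = _coupled_cohort(seed=3, n_samples=8)
        truth = {
            sid: em.labels["metacluster"].to_numpy()
            for sid, em in cohort.events.items()
        }
        profiles = cc.median_profile(cohort.events, truth)
        cat = pd.DataFrame(
            {"ligand": ["ICOSL", "GAL9"], "receptor": ["ICOS", "TIM3"]}
        )
        with pytest.warns(UserWarning, match="absent"):
            table = cc.lr_screen(profiles, cat, ["tcell"], ["bcell"],
                                 n_perm=99, seed=1)
        assert set(zip(table["ligand"], table["receptor"])) == {("ICOSL", "ICOS")}

    def test_frequency_screen_recovers_monotone_dependence(self, rng):
        sids = [f"s{i}" for i in range(12)]
        a = np.sort(rng.uniform(5, 40, 12))
        b = 100 / (1 + a)  # monotone function of a
        c = rng.uniform(10, 20, 12)
        freq = pd.DataFrame({"mcA": a, "mcB": b, "mcC": c}, index=sids)
        table = cc.frequency_screen(freq, ["mcA"], ["mcB", "mcC"],
                                    n_perm=999, seed=5)
        row = table[table["population_b"] == "mcB"].iloc[0]
        assert row["significant"]
        assert row["signed"] < 0  # decreasing monotone dependence
        # self-pairing excluded
        assert not ((table["population_a"] == table["population_b"]).any())

    def test_screen_requires_complete_pairs(self):
        freq = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]},
                            index=["s1", "s2"])
        with pytest.raises(ValueError, match="complete"):
            cc.frequency_screen(freq, ["a"], ["b"], min_n=4)
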