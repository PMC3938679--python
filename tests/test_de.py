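"""Filtering and moderated-t contracts, each checked against an
independent closed-form or brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhexpress.de import (
    EBayesPrior,
    ModeratedPairedTTest,
    bh_adjust,
    call_degs,
    estimate_prior,
    filter_probes,
    moderated_t,
    paired_diffs,
    signed_fold_change,
)
from rhexpress.exceptions import (
    DataError,
    DegenerateDataError,
    DesignError,
    InvalidParameterError,
)
from rhexpress.simulate import SimConfig, generate_paired_experiment, generate_variances

from conftest import make_paired_matrix


class TestFilterProbes:
    def test_toy_matrix_keeps_single_probe(self, toy_paired):
        # flat: SD 0; low: max < 3; dim: SD ~0.075 < 0.1; keep: passes both
        out = filter_probes(toy_paired)
        assert list(out.probe_ids) == ["keep"]

    def test_all_below_three_removed(self):
        m = make_paired_matrix({"p": (2.9, 2.9, 2.9, 2.9)})
        assert filter_probes(m).n_probes == 0

    def test_boundary_is_strict(self):
        m = make_paired_matrix({"p": (3.0, 3.0, 3.0, 3.0)})
        assert filter_probes(m).n_probes == 0

    def test_sample_set_and_probe_order_preserved(self, toy_paired):
        out = filter_probes(toy_paired, min_expr=0.0, min_sd=0.0)
        assert list(out.sample_ids) == list(toy_paired.sample_ids)
        assert list(out.probe_ids) == [
            p for p in toy_paired.probe_ids
            if p in set(out.probe_ids)
        ]

    def test_empty_matrix_rejected(self, toy_paired):
        empty = toy_paired.subset_probes([])
        with pytest.raises(DataError):
            filter_probes(empty)


class TestPairedDiffs:
    def test_direct_arithmetic(self):
        m = make_paired_matrix({"p": (5, 7, 6, 6.5)})
        d = paired_diffs(m)
        assert d.loc["p"].tolist() == [2.0, 0.5]
        assert d.loc["p"].mean() == 1.25

    def test_identical_conditions_give_zero(self):
        m = make_paired_matrix({"p": (4, 4, 6, 6), "q": (1, 1, 2, 2)})
        assert (paired_diffs(m) == 0).all().all()

    def test_label_swap_flips_only_that_pair(self):
        m = make_paired_matrix({"p": (5, 7, 6, 6.5)})
        swapped = m.samples.copy()
        swapped.loc["c1", "condition"] = "treated"
        swapped.loc["t1", "condition"] = "control"
        m2 = make_paired_matrix({"p": (5, 7, 6, 6.5)})
        m2.samples = swapped
        d1, d2 = paired_diffs(m), paired_diffs(m2)
        assert d2.loc["p", "pair1"] == -d1.loc["p", "pair1"]
        assert d2.loc["p", "pair2"] == d1.loc["p", "pair2"]

    def test_unpaired_sample_named_in_error(self):
        m = make_paired_matrix({"p": (5, 7, 6, 6.5)})
        m.samples.loc["t2", "pair_id"] = ""
        with pytest.raises(DesignError, match="t2"):
            paired_diffs(m)


class TestEstimatePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(50, 0.07), df_resid=3)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.07, rel=1e-9)  # geometric mean

    def test_parameter_recovery_from_simulated_prior(self):
        # sigma^2 ~ prior(d0=4, s0^2=0.05); s^2 ~ sigma^2 * chi2_3 / 3
        rng = np.random.default_rng(101)
        sigma_sq = generate_variances(20_000, 4.0, 0.05, seed=rng, var_floor=0.0)
        s_sq = sigma_sq * rng.chisquare(3, 20_000) / 3
        prior = estimate_prior(s_sq, df_resid=3)
        assert prior.d0 == pytest.approx(4.0, rel=0.25)
        assert prior.s0_sq == pytest.approx(0.05, rel=0.10)

    def test_extreme_variance_ratio_yields_finite_small_d0(self):
        prior = estimate_prior(np.array([1e-3, 1e3]), df_resid=3)
        assert np.isfinite(prior.d0) and prior.d0 > 0

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DegenerateDataError):
            estimate_prior(np.zeros(10), df_resid=3)


class TestModeratedT:
    def test_d0_zero_reduces_to_classic_paired_t(self):
        diffs = np.array([2.0, 0.5, 1.0, 1.5])
        prior = EBayesPrior(d0=0.0, s0_sq=1.0)
        s_tilde, t, df, p = moderated_t(
            np.array([diffs.mean()]), np.array([diffs.var(ddof=1)]), 3, prior, 4
        )
        t_ref, p_ref = stats.ttest_1samp(diffs, 0.0)
        assert t[0] == pytest.approx(t_ref, rel=1e-12)
        assert p[0] == pytest.approx(p_ref, rel=1e-12)
        assert df[0] == 3

    def test_zero_mean_diff_gives_p_one(self):
        prior = EBayesPrior(d0=4.0, s0_sq=0.05)
        _, t, _, p = moderated_t(np.zeros(3), np.full(3, 0.1), 3, prior, 4)
        assert np.all(t == 0) and np.all(p == 1)

    def test_infinite_prior_uses_normal_tail(self):
        prior = EBayesPrior(d0=np.inf, s0_sq=1.0)
        _, t, df, p = moderated_t(np.array([0.98]), np.array([5.0]), 3, prior, 4)
        assert t[0] == pytest.approx(1.96)
        assert np.isinf(df[0])
        assert p[0] == pytest.approx(2 * stats.norm.sf(1.96), rel=1e-12)

    def test_zero_posterior_variance_flagged_extremes(self):
        prior = EBayesPrior(d0=0.0, s0_sq=1.0)
        _, t, _, p = moderated_t(np.array([1.0, 0.0]), np.zeros(2), 3, prior, 4)
        assert np.isinf(t[0]) and p[0] == 0.0
        assert t[1] == 0.0 and p[1] == 1.0

    @given(
        st.lists(st.floats(-3, 3), min_size=2, max_size=8).map(np.array),
        st.floats(0.01, 2.0),
        st.floats(0.1, 20.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shrinkage_direction_property(self, mean_diff, s0_sq, d0):
        s_sq = np.abs(mean_diff) + 0.01  # arbitrary positive variances
        prior = EBayesPrior(d0=d0, s0_sq=s0_sq)
        s_tilde, _, _, _ = moderated_t(mean_diff, s_sq, 3, prior, 4)
        lo = np.minimum(s_sq, s0_sq) - 1e-12
        hi = np.maximum(s_sq, s0_sq) + 1e-12
        assert np.all(s_tilde >= lo) and np.all(s_tilde <= hi)

    def test_monotone_in_mean_diff(self):
        prior = EBayesPrior(d0=4.0, s0_sq=0.05)
        mags = np.linspace(0, 3, 20)
        _, t, _, _ = moderated_t(mags, np.full(20, 0.1), 3, prior, 4)
        assert np.all(np.diff(np.abs(t)) >= 0)


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * G / j."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    g = len(p)
    q_sorted = [
        min(min(p[order[j]] * g / (j + 1) for j in range(i, g)), 1.0)
        for i in range(g)
    ]
    out = np.empty(g)
    out[order] = q_sorted
    return out


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 13)))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_dominates_input_and_capped(self, p):
        out = bh_adjust(p)
        assert np.all(out <= 1.0 + 1e-12)
        assert np.all(out >= np.maximum(np.asarray(p), np.nextafter(0.0, 1.0)) - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_adjust([0.5, 1.5])


class TestCallDegs:
    def table(self, rows):
        df = pd.DataFrame(rows, columns=["fch", "fdr"])
        df.index = [f"p{i}" for i in range(len(rows))]
        df["mean_log2_diff"] = np.sign(df["fch"]) * np.log2(np.abs(df["fch"]))
        return df

    def test_boundary_fch_not_a_deg(self):
        out = call_degs(self.table([(1.5, 0.01)]))
        assert not out["is_deg"].any()

    def test_toy_table_two_degs(self):
        out = call_degs(self.table([(2.0, 0.05), (-1.8, 0.09), (3.0, 0.2), (1.2, 0.01)]))
        degs = out[out["is_deg"]]
        assert len(degs) == 2
        assert set(degs["direction"]) == {"up", "down"}

    def test_sorted_by_abs_fch_with_lexicographic_ties(self):
        out = call_degs(self.table([(2.0, 0.05), (-2.0, 0.05), (3.0, 0.01)]))
        assert list(out.index) == ["p2", "p0", "p1"]


class TestEndToEndStage:
    def test_d0_zero_stage_equals_textbook_paired_t(self, rng):
        """Whole stage with no shrinkage = scipy's paired t-test."""
        for _ in range(100):
            values = rng.normal(7, 1, size=(5, 8))
            m = make_paired_matrix({f"g{i}": values[i] for i in range(5)})
            res = ModeratedPairedTTest(m).fit(prior=EBayesPrior(0.0, 1.0))
            ctrl = values[:, 0::2]
            trt = values[:, 1::2]
            t_ref, p_ref = stats.ttest_rel(trt, ctrl, axis=1)
            np.testing.assert_allclose(res.table["t_mod"], t_ref, rtol=1e-10)
            np.testing.assert_allclose(res.table["p"], p_ref, rtol=1e-10)

    def test_null_type_one_error_calibrated(self):
        cfg = SimConfig(seed=33, n_probes_shared=5000, n_probes_plus_only=0, pi_de=0.0)
        matrix, _ = generate_paired_experiment(cfg)
        res = ModeratedPairedTTest(matrix).fit()
        frac = (res.table["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res.table))
        assert abs(frac - 0.05) < 3 * se
        assert int(res.call_degs()["is_deg"].sum()) <= 5

    def test_planted_effects_detected(self):
        cfg = SimConfig(seed=44, n_probes_shared=5000, n_probes_plus_only=0, pi_de=0.1)
        matrix, truth = generate_paired_experiment(cfg)
        res = ModeratedPairedTTest(matrix).fit()
        degs = res.call_degs()
        called = set(degs.index[degs["is_deg"]])
        responsive = set(truth.responsive_probes)
        sensitivity = len(called & responsive) / len(responsive)
        fdp = len(called - responsive) / max(len(called), 1)
        assert sensitivity >= 0.8
        assert fdp <= 0.2

    def test_fdr_monotone_in_p(self):
        cfg = SimConfig(seed=3, n_probes_shared=500, n_probes_plus_only=0)
        matrix, _ = generate_paired_experiment(cfg)
        res = ModeratedPairedTTest(matrix).fit()
        tab = res.table.sort_values("p")
        assert np.all(np.diff(tab["fdr"]) >= -1e-12)

    def test_fch_threshold_equivalent_to_log2_threshold(self):
        d = np.array([-2.0, -0.3, 0.0, 0.3, 2.0])
        fch = signed_fold_change(d)
        assert np.array_equal(np.abs(fch) > 1.5, np.abs(d) > np.log2(1.5))
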