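"""Generator contracts: reproducibility, planted structure, and the
distributional promises downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhexpress.exceptions import InvalidParameterError
from rhexpress.simulate import (
    CohortConfig,
    SimConfig,
    generate_annotation,
    generate_cohort,
    generate_paired_experiment,
    generate_variances,
    random_gene_sets,
    simulate_rhe_dataset,
    truth_gene_sets,
)


class TestGenerateVariances:
    def test_empty(self):
        assert generate_variances(0, 4.0, 0.05, seed=1).size == 0

    def test_degenerate_prior_returns_constant(self):
        out = generate_variances(5, np.inf, 0.04, seed=1)
        assert np.all(out == 0.04)

    def test_inverse_mean_matches_analytic_expectation(self):
        # E(1/sigma^2) = 1/s0^2 under the scaled inverse chi-square prior
        out = generate_variances(50_000, 4.0, 0.05, seed=42)
        assert np.mean(1.0 / out) == pytest.approx(20.0, rel=0.02)

    @pytest.mark.parametrize("n,d0,s0", [(-1, 4, 0.05), (5, 4, 0.0), (5, 4, -1.0), (5, 0, 0.05)])
    def test_invalid_parameters_rejected(self, n, d0, s0):
        with pytest.raises(InvalidParameterError):
            generate_variances(n, d0, s0, seed=0)

    def test_floor_applied(self):
        out = generate_variances(1000, 0.05, 1e-7, seed=0, var_floor=1e-8)
        assert out.min() >= 1e-8


class TestPairedExperiment:
    def test_reproducible_byte_identical(self):
        cfg = SimConfig(seed=7, n_probes_shared=300, n_probes_plus_only=60)
        m1, t1 = generate_paired_experiment(cfg)
        m2, t2 = generate_paired_experiment(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_series_equal(t1.true_lfc, t2.true_lfc)
        assert t1.responsive_probes == t2.responsive_probes

    def test_no_effects_when_pi_de_zero(self):
        cfg = SimConfig(seed=1, n_probes_shared=200, n_probes_plus_only=0, pi_de=0.0)
        _, truth = generate_paired_experiment(cfg)
        assert truth.responsive_probes == frozenset()
        assert (truth.true_lfc == 0).all()

    def test_lfc_nonzero_exactly_on_responsive(self):
        cfg = SimConfig(seed=5, n_probes_shared=500, n_probes_plus_only=100, pi_de=0.3)
        _, truth = generate_paired_experiment(cfg)
        nonzero = frozenset(truth.true_lfc.index[truth.true_lfc != 0])
        assert nonzero == truth.responsive_probes

    def test_noiseless_limit_recovers_effects_exactly(self):
        cfg = SimConfig(
            seed=2, n_probes_shared=50, n_probes_plus_only=0,
            s0_sq=0.0, subject_sd=0.0, pi_de=0.5,
        )
        matrix, truth = generate_paired_experiment(cfg)
        diffs = (
            matrix.values[["RHE_trea_1", "RHE_trea_2"]].to_numpy()
            - matrix.values[["RHE_cont_1", "RHE_cont_2"]].to_numpy()
        )
        expected = np.broadcast_to(truth.true_lfc.to_numpy()[:, None], diffs.shape)
        # exact up to float associativity of (mu + delta) - mu
        np.testing.assert_allclose(diffs, expected, atol=1e-12)

    def test_mean_paired_difference_unbiased_for_planted_effect(self):
        cfg = SimConfig(seed=11, n_probes_shared=5000, n_probes_plus_only=0, pi_de=0.1)
        matrix, truth = generate_paired_experiment(cfg)
        trt = matrix.samples.index[matrix.samples.condition == "treated"]
        ctl = matrix.samples.index[matrix.samples.condition == "control"]
        diff = matrix.values[trt].to_numpy() - matrix.values[ctl].to_numpy()
        resp = truth.true_lfc != 0
        err = diff.mean(axis=1)[resp] - truth.true_lfc[resp]
        # mean estimation error over responsive probes ~ N(0, mean(2*sigma^2/4)/n)
        se = np.sqrt((2 * truth.true_sigma_sq[resp] / cfg.n_pairs).mean() / resp.sum())
        assert abs(err.mean()) < 3 * se


class TestAnnotation:
    def test_empty(self):
        ann = generate_annotation(0, 0, seed=1)
        assert len(ann.probe_ids) == 0

    def test_single_probe_per_gene_is_injective(self):
        ann = generate_annotation(100, 20, max_probes_per_gene=1, seed=3)
        assert ann.table["gene_id"].is_unique

    def test_platform_tags_count(self):
        ann = generate_annotation(200, 50, seed=4)
        only_plus = ann.table["platforms"].map(lambda p: p == frozenset({"APlus2"}))
        assert int(only_plus.sum()) == 50
        assert len(ann.probes_on("A2")) == 200
        assert len(ann.probes_on("APlus2")) == 250

    def test_every_probe_has_one_gene(self):
        ann = generate_annotation(100, 10, max_probes_per_gene=4, seed=5)
        assert not ann.table["gene_id"].isna().any()
        sizes = ann.table.groupby("gene_id").size()
        assert sizes.between(1, 4).all()


class TestCohort:
    def cfg(self, **kw):
        base = dict(
            n_patients_per_arm=4, n_genes=300, n_dysreg_genes=80, noise_sd=0.02,
        )
        base.update(kw)
        return CohortConfig(**base)

    def test_placebo_like_arm_leaves_baseline(self):
        cfg = self.cfg(arms={"placebo": None}, noise_sd=0.0)
        matrix, truth = generate_cohort(cfg, seed=1)
        ls0 = matrix.samples_where(condition="LS", timepoint="baseline")
        ls2 = matrix.samples_where(condition="LS", timepoint="week2")
        assert np.allclose(
            matrix.values[ls0].mean(axis=1), matrix.values[ls2].mean(axis=1)
        )

    def test_full_recovery_arm_returns_to_nl(self):
        cfg = self.cfg(arms={"cure": 1.0}, noise_sd=0.0)
        matrix, _ = generate_cohort(cfg, seed=2)
        nl = matrix.samples_where(condition="NL")
        ls2 = matrix.samples_where(condition="LS", timepoint="week2")
        assert np.allclose(matrix.values[nl].mean(axis=1), matrix.values[ls2].mean(axis=1))

    def test_recovery_fraction_tail_matches_beta_cdf(self):
        cfg = self.cfg(n_genes=2500, n_dysreg_genes=2000, arms={"trt": (6.0, 2.0)})
        _, truth = generate_cohort(cfg, seed=3)
        r = truth.true_recovery_frac["trt"]
        expected = stats.beta.sf(0.75, 6, 2)
        se = np.sqrt(expected * (1 - expected) / len(r))
        assert abs((r >= 0.75).mean() - expected) < 3 * se

    def test_bad_beta_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_cohort(self.cfg(arms={"trt": (0.0, 2.0)}), seed=0)

    def test_dysreg_gene_override_outside_universe_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_cohort(self.cfg(), seed=0, genes=["a", "b"], dysreg_genes=["zzz"])

    def test_reproducible(self):
        cfg = self.cfg()
        m1, _ = generate_cohort(cfg, seed=9)
        m2, _ = generate_cohort(cfg, seed=9)
        pd.testing.assert_frame_equal(m1.values, m2.values)


class TestGeneSets:
    def test_truth_sets_split_by_direction(self):
        matrix, ann, truth = simulate_rhe_dataset(
            SimConfig(seed=6, n_probes_shared=400, n_probes_plus_only=80, pi_de=0.2)
        )
        sets = truth_gene_sets(truth, ann)
        up = set(sets["RESPONSIVE_UP"].members)
        down = set(sets["RESPONSIVE_DOWN"].members)
        genes_up = set(
            ann.table.loc[truth.true_lfc.index[truth.true_lfc > 0], "gene_id"]
        )
        genes_down = set(
            ann.table.loc[truth.true_lfc.index[truth.true_lfc < 0], "gene_id"]
        )
        assert up == genes_up and down == genes_down

    def test_random_sets_respect_universe_and_size(self):
        coll = random_gene_sets([f"g{i}" for i in range(100)], 5, 10, seed=1)
        assert len(coll) == 5
        for gs in coll:
            assert len(gs) == 10
            assert all(m.startswith("g") for m in gs.members)
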