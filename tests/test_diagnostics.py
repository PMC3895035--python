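"""NPDE machinery, calibration tests, shrinkage, GOF tables."""

import copy
import dataclasses

import numpy as np
import pytest

from azapd import (
    AcetazolamidePD,
    SaemConfig,
    compute_npde,
    generate_cohort,
    npde_tests,
    study_design,
    shrinkage,
)
from azapd.cohort import CountSpec
from azapd.model import simulate_observation_matrix
from azapd.saem import BatchData, CovariateModel


class TestShrinkage:
    def test_definition_identities(self):
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 0.10, 2000)
        assert shrinkage(etas, float(etas.std(ddof=1))) == pytest.approx(0.0)
        assert shrinkage(np.zeros(50), 0.3) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        # sd(eta) = 0.05 against omega = 0.10 gives 50% shrinkage
        etas = np.array([-0.05, 0.05, -0.05, 0.05]) * np.sqrt(4 / 3) / np.sqrt(1)
        got = shrinkage(etas, 0.10)
        assert got == pytest.approx(1 - np.std(etas, ddof=1) / 0.10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            shrinkage(np.zeros(10), 0.0)
        with pytest.raises(ValueError):
            shrinkage(np.array([0.1]), 0.2)


class TestNpdeTests:
    def test_calibrated_on_standard_normal_samples(self):
        """Under N(0,1) data the three p-values are non-significant in
        roughly 95% of seeds."""
        above = 0
        n_seeds = 40
        for seed in range(n_seeds):
            values = np.random.default_rng(seed).standard_normal(1000)
            out = npde_tests(values)
            above += all(p > 0.05 for p in out.values())
        assert above >= int(0.80 * n_seeds)

    def test_location_shift_detected(self):
        values = np.random.default_rng(1).standard_normal(1000) + 1.0
        assert npde_tests(values)["wilcoxon_p"] < 1e-3

    def test_scale_inflation_detected(self):
        values = np.random.default_rng(2).standard_normal(1000) * 3.0
        assert npde_tests(values)["fisher_var_p"] < 1e-3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            npde_tests(np.ones(100))
        with pytest.raises(ValueError):
            npde_tests(np.arange(5))


@pytest.fixture(scope="module")
def calibration_batch(published):
    """A 200-subject cohort simulated from the published model."""
    design = study_design(seed=31, n_subjects=200,
                          mv_counts=CountSpec(6, 1.0, 3, 9),
                          bg_counts=CountSpec(3, 1.0, 1, 6))
    dataset = generate_cohort(published, design)
    return BatchData(dataset, published.fixed, CovariateModel())


class TestComputeNpde:
    def test_calibrated_under_the_true_model(self, calibration_batch, published):
        """Across replicate cohorts simulated from the model the npde are
        standard normal: pooled mean ~0, pooled variance ~1, and the
        location/scale tests are predominantly non-significant."""
        batches = [calibration_batch]
        for seed in (32, 33):
            design = study_design(seed=seed, n_subjects=200,
                                  mv_counts=CountSpec(6, 1.0, 3, 9),
                                  bg_counts=CountSpec(3, 1.0, 1, 6))
            batches.append(BatchData(generate_cohort(published, design),
                                     published.fixed, CovariateModel()))
        variances, means, p_ok, p_total = [], [], 0, 0
        for batch in batches:
            result = compute_npde(batch, published, n_sim=500, seed=7)
            means.append(result.npde.mean())
            variances.append(result.npde.var())
            for label in ("BICAR", "MV", "PACO2"):
                for test in ("wilcoxon_p", "fisher_var_p"):
                    p_total += 1
                    p_ok += result.tests[label][test] > 0.05
        assert abs(np.mean(means)) < 0.05
        assert np.mean(variances) == pytest.approx(1.0, abs=0.05)
        assert p_ok >= int(0.8 * p_total)

    def test_detects_a_misspecified_baseline(self, calibration_batch, published):
        wrong = dataclasses.replace(
            published, fixed=dataclasses.replace(published.fixed,
                                                 paco2_0_pop=70.0))
        result = compute_npde(calibration_batch, wrong, n_sim=300, seed=7)
        assert result.tests["PACO2"]["wilcoxon_p"] < 1e-6

    def test_stable_in_the_number_of_simulations(self, published):
        """npde values stabilise as n_sim grows: repeat-to-repeat SD under
        0.05 at n_sim=2000 and roughly halved relative to n_sim=500 (the
        decorrelation noise scales as sqrt(L/n_sim))."""
        design = study_design(seed=33, n_subjects=12,
                              mv_counts=CountSpec(5, 1.0, 3, 7))
        batch = BatchData(generate_cohort(published, design),
                          published.fixed, CovariateModel())
        sd = {}
        for n_sim in (500, 2000):
            reps = np.stack([
                compute_npde(batch, published, n_sim=n_sim, seed=100 + r).npde
                for r in range(3)
            ])
            sd[n_sim] = reps.std(axis=0).mean()
        assert sd[2000] < 0.05
        assert sd[2000] < 0.7 * sd[500]

    def test_invariant_to_observation_value_monotone_agreement(self, published):
        """An observation at the componentwise simulated median maps to
        npde near zero."""
        design = study_design(seed=35, n_subjects=5)
        dataset = generate_cohort(published, design)
        batch = BatchData(dataset, published.fixed, CovariateModel())
        sims = simulate_observation_matrix(batch, published, 501,
                                           np.random.default_rng(3))
        batch_med = copy.copy(batch)
        batch_med.obs_y = np.median(sims, axis=1)
        result = compute_npde(batch_med, published, n_sim=500, seed=9)
        # medians of the decorrelated clouds: centred ranks
        assert abs(result.npde.mean()) < 0.25
        pd_vals = result.table["pd"].to_numpy()
        assert np.all(pd_vals > 0) and np.all(pd_vals < 1)

    def test_small_n_sim_rejected(self, calibration_batch, published):
        with pytest.raises(ValueError):
            compute_npde(calibration_batch, published, n_sim=20, seed=1)


@pytest.fixture(scope="module")
def quick_fit(published):
    dataset = generate_cohort(published, study_design(seed=37, n_subjects=30))
    model = AcetazolamidePD(dataset, init=published)
    return model.fit(SaemConfig(n_burn=40, n_smooth=80, compute_rse=False,
                                seed=2))


class TestGof:
    def test_table_row_count_equals_observation_count(self, quick_fit):
        out = quick_fit.gof()
        assert len(out["table"]) == quick_fit.model.batch.m

    def test_identity_slope_near_one_for_well_specified_fit(self, quick_fit):
        for slope in out_slopes(quick_fit):
            assert 0.9 < slope < 1.1

    def test_noise_free_observations_match_predictions_exactly(self, published):
        truth = dataclasses.replace(
            published,
            random=dataclasses.replace(
                published.random, omega_bicar0=0, omega_kout=0, omega_mv0=0,
                omega_paco2_0=0, omega_pow_mv_paco2=0),
            residual=dataclasses.replace(
                published.residual, sigma_bicar=0, sigma_mv=0, sigma_paco2=0))
        dataset = generate_cohort(truth, study_design(seed=39, n_subjects=5))
        model = AcetazolamidePD(dataset, init=published)
        pred = model.predictions(truth)
        np.testing.assert_allclose(pred, model.batch.obs_y, rtol=1e-8)


def out_slopes(fit):
    return fit.gof()["slopes"].values()
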