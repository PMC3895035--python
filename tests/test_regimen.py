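"""Dose-regimen Monte-Carlo simulator."""

import dataclasses

import numpy as np
import pytest

from azapd import (
    RegimenSpec,
    responder_proportions,
    simulate_regimen,
    summarize_regimens,
)
from azapd.cohort import DesignConfig


def _deterministic_design():
    """Median covariates, no binary flags: one deterministic subject."""
    return DesignConfig(saps2_cv=1e-12, chloride_sd=1e-12,
                        p_corticosteroid=0.0, p_female=0.0,
                        p_volume_assist=0.0, p_furosemide=0.0)


def _no_bsv(published):
    return dataclasses.replace(
        published, random=dataclasses.replace(
            published.random, omega_bicar0=0, omega_kout=0, omega_mv0=0,
            omega_paco2_0=0, omega_pow_mv_paco2=0))


class TestRegimenSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            RegimenSpec(daily_dose=-1)
        with pytest.raises(ValueError):
            RegimenSpec(daily_dose=500, horizon=2.0, duration=1.0)
        spec = RegimenSpec(daily_dose=1000, doses_per_day=2, duration=2.0,
                           horizon=1.0)
        np.testing.assert_allclose(spec.dose_times(), [0, 0.5, 1.0, 1.5])
        assert spec.dose_amount == 500.0


class TestSimulateRegimen:
    def test_zero_dose_leaves_every_subject_unchanged(self, published):
        deltas = simulate_regimen(published, RegimenSpec(daily_dose=0.0),
                                  n_subjects=500, seed=1,
                                  include_residual=False)
        np.testing.assert_allclose(deltas["delta_mv"], 0.0, atol=1e-8)
        np.testing.assert_allclose(deltas["delta_paco2"], 0.0, atol=1e-8)

    def test_huge_dose_approaches_analytic_ceiling(self, published):
        """At saturating dose the bicarbonate steady state is Bicar0/2 and
        the MV/PaCO2 changes follow the closed-form chain."""
        truth = _no_bsv(published)
        fx = truth.fixed
        regimen = RegimenSpec(daily_dose=1e6, doses_per_day=1,
                              duration=40.0, horizon=40.0)
        deltas = simulate_regimen(truth, regimen, n_subjects=3, seed=2,
                                  design=_deterministic_design(), mode="psv",
                                  include_residual=False)
        b0 = fx.bicar0_pop
        mv0 = fx.mv0_pop * (fx.bicar_ref / b0) ** fx.pow_bicar_mv
        mv_inf = fx.mv0_pop * (fx.bicar_ref / (b0 / 2)) ** fx.pow_bicar_mv
        expected_dmv = mv_inf - mv0
        expected_dpaco2 = fx.paco2_0_pop * (
            0.5 ** (fx.pow_bicar_mv * fx.pow_mv_paco2) - 1.0)
        np.testing.assert_allclose(deltas["delta_mv"], expected_dmv, rtol=1e-3)
        np.testing.assert_allclose(deltas["delta_paco2"], expected_dpaco2,
                                   rtol=1e-3)

    def test_paired_subjects_make_dose_response_monotone(self, published):
        """Common random numbers: every dose increment helps every subject."""
        frames = {
            dose: simulate_regimen(published, RegimenSpec(daily_dose=dose),
                                   n_subjects=2000, seed=3, mode="psv")
            for dose in (250.0, 500.0, 1000.0, 2000.0)
        }
        for lo, hi in [(250.0, 500.0), (500.0, 1000.0), (1000.0, 2000.0)]:
            assert np.all(frames[hi]["delta_mv"] >= frames[lo]["delta_mv"] - 1e-12)
            assert np.all(frames[hi]["delta_paco2"] <= frames[lo]["delta_paco2"] + 1e-12)

    def test_psv_exceeds_va_by_the_mode_multiplier(self, published):
        """Matched virtual subjects: the MV change under volume assist is
        exactly 0.92 times the pressure-support change."""
        design = dataclasses.replace(_deterministic_design(),
                                     saps2_cv=0.3, chloride_sd=5.0)
        common = dict(n_subjects=1000, seed=4, design=design,
                      include_residual=False)
        psv = simulate_regimen(published, RegimenSpec(daily_dose=1000),
                               mode="psv", **common)
        va = simulate_regimen(published, RegimenSpec(daily_dose=1000),
                              mode="va", **common)
        np.testing.assert_allclose(va["delta_mv"],
                                   0.92 * psv["delta_mv"], rtol=1e-10)
        # PaCO2 is insensitive to the ventilator mode (the multiplier
        # cancels in the MV ratio)
        np.testing.assert_allclose(va["delta_paco2"], psv["delta_paco2"],
                                   rtol=1e-10)

    def test_residual_error_flag_widens_the_delta_distribution(self, published):
        latent = simulate_regimen(published, RegimenSpec(daily_dose=1000),
                                  n_subjects=4000, seed=5,
                                  include_residual=False)
        observed = simulate_regimen(published, RegimenSpec(daily_dose=1000),
                                    n_subjects=4000, seed=5)
        assert observed["delta_mv"].std() > latent["delta_mv"].std()


class TestResponderProportions:
    def test_all_above_threshold(self):
        import pandas as pd

        deltas = pd.DataFrame({"delta_mv": [1.0, 2.0], "delta_paco2": [-6.0, -7.0],
                               "mode": ["psv", "psv"]})
        out = responder_proportions(deltas)
        assert out["all"]["p_mv"] == 1.0
        assert out["all"]["p_paco2"] == 1.0

    def test_strict_inequality_at_the_threshold(self):
        import pandas as pd

        deltas = pd.DataFrame({"delta_mv": [0.75], "delta_paco2": [-5.0],
                               "mode": ["va"]})
        out = responder_proportions(deltas)
        assert out["all"]["p_mv"] == 0.0
        assert out["all"]["p_paco2"] == 0.0

    def test_empty_input_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            responder_proportions(pd.DataFrame(columns=["delta_mv"]))

    def test_proportions_stable_across_seeds(self, published):
        estimates = [
            responder_proportions(
                simulate_regimen(published, RegimenSpec(daily_dose=1000),
                                 n_subjects=10_000, seed=s, mode="psv")
            )["all"]["p_mv"]
            for s in (11, 12, 13)
        ]
        assert np.ptp(estimates) < 0.02


def test_summary_table_covers_all_cells(published):
    summary = summarize_regimens(published, [250, 1000], n_subjects=2000, seed=6)
    assert len(summary) == 4  # 2 doses x 2 modes
    assert set(summary["mode"]) == {"psv", "va"}
    psv = summary[summary["mode"] == "psv"].sort_values("daily_dose")
    assert psv["median_delta_mv"].is_monotonic_increasing
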