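"""Structural model: turnover ODE, covariate relations, MV/PaCO2 chain."""

import numpy as np
import pytest

from azapd import Covariates
from azapd.kinetics import DoseEvent, Drug
from azapd.turnover import (
    bicar_trajectory,
    covariate_bicar0,
    derive_kin,
    mv_baseline,
    mv_from_bicar,
    paco2_from_mv,
    simulate_chain,
)

BID = [DoseEvent(0.5 * i, 500.0) for i in range(8)]


class TestDeriveKin:
    def test_published_values(self):
        assert derive_kin(35.4, 0.314) == pytest.approx(11.1156)

    def test_degenerate_cases(self):
        assert derive_kin(35.4, 0.0) == 0.0
        assert derive_kin(1.0, 1.0) == 1.0


class TestCovariateBicar0:
    def test_reference_covariates_leave_baseline_unchanged(self, published):
        assert covariate_bicar0(35.4, Covariates(), published.fixed) == pytest.approx(35.4)

    def test_corticosteroid_multiplier(self, published):
        cov = Covariates(corticosteroid=True)
        assert covariate_bicar0(35.4, cov, published.fixed) == pytest.approx(38.94)

    def test_chloride_power(self, published):
        cov = Covariates(chloride=110.0)
        expected = 35.4 * 1.1 ** -1.17
        got = covariate_bicar0(35.4, cov, published.fixed)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(31.66, rel=1e-3)

    def test_invalid_covariates_rejected(self):
        with pytest.raises(ValueError):
            Covariates(saps2=0.0)
        with pytest.raises(ValueError):
            Covariates(chloride=-5.0)


class TestBicarTrajectory:
    def test_equilibrium_without_doses(self, reference_individual, published):
        t = np.linspace(0, 10, 101)
        b = bicar_trajectory(reference_individual, published.fixed, [], [], t)
        np.testing.assert_allclose(b, 35.4, rtol=1e-6)

    def test_clamped_amount_reaches_closed_form_steady_state(
            self, reference_individual, published):
        # constant A = A50 gives B_ss = Bicar0 / (1 + Emax/2)
        b = bicar_trajectory(reference_individual, published.fixed, [], [],
                             np.array([0.0, 40.0]),
                             ace_amount_fn=lambda t: 163.0)
        assert b[-1] == pytest.approx(35.4 / 1.5, rel=1e-4)

    def test_clamped_amount_limit_of_maximal_stimulation(
            self, reference_individual, published):
        b = bicar_trajectory(reference_individual, published.fixed, [], [],
                             np.array([0.0, 60.0]),
                             ace_amount_fn=lambda t: 1e9)
        assert b[-1] == pytest.approx(35.4 / 2.0, rel=1e-4)

    def test_exact_and_runge_kutta_integrators_agree(
            self, reference_individual, published):
        fur = [DoseEvent(float(i), 40.0, Drug.FUROSEMIDE) for i in range(4)]
        t = np.linspace(0, 4, 49)
        exact = bicar_trajectory(reference_individual, published.fixed, BID, fur, t)
        rk = bicar_trajectory(reference_individual, published.fixed, BID, fur, t,
                              method="rk")
        np.testing.assert_allclose(exact, rk, rtol=1e-6)

    def test_bicar_monotone_in_total_dose(self, reference_individual, published):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        prev = None
        for amount in (0.0, 250.0, 500.0, 1000.0):
            doses = [DoseEvent(0.5 * i, amount) for i in range(8)]
            b = bicar_trajectory(reference_individual, published.fixed,
                                 doses, [], t)
            if prev is not None:
                assert np.all(b <= prev + 1e-9)
            prev = b

    def test_bad_grid_rejected(self, reference_individual, published):
        with pytest.raises(ValueError):
            bicar_trajectory(reference_individual, published.fixed, [], [],
                             np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            bicar_trajectory(reference_individual, published.fixed, [], [],
                             np.array([2.0, 1.0]))


class TestAlgebraicChain:
    def test_mv_at_reference_bicarbonate(self, reference_individual, published):
        got = mv_from_bicar(reference_individual, published.fixed,
                            Covariates(), 37.5)
        assert got == pytest.approx(11.1)

    def test_mv_multipliers_female_volume_assist(self, reference_individual,
                                                 published):
        cov = Covariates(female=True, volume_assist=True)
        got = mv_from_bicar(reference_individual, published.fixed, cov, 37.5)
        assert got == pytest.approx(11.1 * 0.92 * 0.82)
        assert got == pytest.approx(8.37, rel=1e-3)

    def test_mv_ceiling_at_halved_bicarbonate(self, reference_individual,
                                              published):
        got = mv_from_bicar(reference_individual, published.fixed,
                            Covariates(), 18.75)
        assert got == pytest.approx(11.1 * 2 ** 0.67)
        assert got == pytest.approx(17.66, rel=1e-3)

    def test_paco2_at_baseline_mv(self, reference_individual):
        assert paco2_from_mv(reference_individual, 9.3, 9.3) == pytest.approx(54.4)

    def test_paco2_halves_scale_with_power(self, reference_individual):
        got = paco2_from_mv(reference_individual, 2 * 9.3, 9.3)
        assert got == pytest.approx(54.4 * 2 ** -0.71)
        assert got == pytest.approx(33.3, rel=1e-2)

    def test_zero_power_makes_paco2_flat(self, published):
        from azapd import IndividualParameters

        ind = IndividualParameters(35.4, 0.314, 11.1, 54.4, 0.0)
        assert paco2_from_mv(ind, 3.0, 12.0) == pytest.approx(54.4)
        assert paco2_from_mv(ind, 25.0, 12.0) == pytest.approx(54.4)

    def test_non_positive_inputs_rejected(self, reference_individual, published):
        with pytest.raises(ValueError):
            mv_from_bicar(reference_individual, published.fixed, Covariates(), 0.0)
        with pytest.raises(ValueError):
            paco2_from_mv(reference_individual, -1.0, 9.3)


class TestChainConsistency:
    @pytest.mark.parametrize("cov", [
        Covariates(),
        Covariates(female=True, volume_assist=True, corticosteroid=True,
                   saps2=72.0, chloride=94.0),
    ])
    def test_chain_identity_at_baseline(self, reference_individual, published, cov):
        """PaCO2(0) equals PaCO2_0 exactly, whatever the covariates."""
        mv0 = mv_from_bicar(reference_individual, published.fixed, cov,
                            reference_individual.bicar0_i)
        assert mv0 == pytest.approx(mv_baseline(reference_individual,
                                                published.fixed, cov))
        paco2 = paco2_from_mv(reference_individual, mv0,
                              mv_baseline(reference_individual, published.fixed, cov))
        assert paco2 == reference_individual.paco2_0_i

    def test_full_chain_under_treatment(self, reference_individual, published):
        t = np.linspace(0, 4, 33)
        traj = simulate_chain(reference_individual, published.fixed,
                              Covariates(), BID, [], t)
        assert traj.bicar[0] == pytest.approx(35.4)
        assert traj.paco2[0] == pytest.approx(54.4)
        # bicarbonate falls, ventilation rises, PaCO2 falls
        assert traj.bicar[-1] < traj.bicar[0]
        assert traj.mv[-1] > traj.mv[0]
        assert traj.paco2[-1] < traj.paco2[0]
        assert np.all(traj.bicar > 0)
        assert np.all(traj.mv > 0)
        assert np.all(traj.paco2 > 0)
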