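"""Structural model: turnover ODE, covariate relations and the
bicarbonate -> minute ventilation -> PaCO2 chain for one subject.

All quantities use days, mg, mmol/L, L/min and mmHg. The bicarbonate
turnover equation starts at equilibrium, so the formation rate is
derived from the baseline: kin = kout * Bicar0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import engine
from .kinetics import Drug, drug_amount, dose_times
from .params import Covariates, FixedEffects, IndividualParameters


def derive_kin(bicar0_i: float, kout_i: float) -> float:
    """Bicarbonate formation rate (mmol/L/day) from the equilibrium condition."""
    if bicar0_i < 0 or kout_i < 0:
        raise ValueError("bicar0_i and kout_i must be non-negative")
    return kout_i * bicar0_i


def covariate_bicar0(bicar0_pop: float, cov: Covariates, fx: FixedEffects) -> float:
    """Covariate-adjusted bicarbonate baseline.

    Multiplicative model: (SAPS II / 50)^beta_saps x
    (chloride / 100)^beta_chloride x cortico_mult if on corticosteroids.
    """
    if cov.saps2 <= 0 or cov.chloride <= 0:
        raise ValueError("saps2 and chloride must be strictly positive")
    out = (
        bicar0_pop
        * (cov.saps2 / 50.0) ** fx.beta_saps
        * (cov.chloride / 100.0) ** fx.beta_chloride
    )
    if cov.corticosteroid:
        out *= fx.cortico_mult
    return out


def mv_multiplier(cov: Covariates, fx: FixedEffects) -> float:
    """Product of the ventilator-mode and sex multipliers on MV0."""
    mult = 1.0
    if cov.volume_assist:
        mult *= fx.va_mult
    if cov.female:
        mult *= fx.female_mult
    return mult


def mv_from_bicar(ind: IndividualParameters, fx: FixedEffects, cov: Covariates,
                  bicar) -> np.ndarray | float:
    """Minute ventilation from bicarbonate through the inverse power law."""
    bicar = np.asarray(bicar, dtype=float)
    if np.any(bicar <= 0):
        raise ValueError("bicar must be strictly positive")
    out = ind.mv0_i * mv_multiplier(cov, fx) * (fx.bicar_ref / bicar) ** fx.pow_bicar_mv
    return float(out) if out.ndim == 0 else out


def mv_baseline(ind: IndividualParameters, fx: FixedEffects, cov: Covariates) -> float:
    """The subject's model minute ventilation at t = 0 (used in the PaCO2 link)."""
    return mv_from_bicar(ind, fx, cov, ind.bicar0_i)


def paco2_from_mv(ind: IndividualParameters, mv, mv_baseline_i: float) -> np.ndarray | float:
    """PaCO2 from minute ventilation relative to the subject's baseline MV."""
    mv = np.asarray(mv, dtype=float)
    if np.any(mv <= 0) or mv_baseline_i <= 0:
        raise ValueError("mv and mv_baseline_i must be strictly positive")
    out = ind.paco2_0_i * (mv_baseline_i / mv) ** ind.pow_mv_paco2_i
    return float(out) if out.ndim == 0 else out


def _split_doses(ace_doses, fur_doses):
    ace = [d for d in (ace_doses or []) if d.amount > 0]
    fur = [d for d in (fur_doses or []) if d.amount > 0]
    for d in ace:
        if d.drug is Drug.FUROSEMIDE:
            raise ValueError("furosemide dose passed in the acetazolamide list")
    for d in fur:
        if d.drug is Drug.ACETAZOLAMIDE:
            raise ValueError("acetazolamide dose passed in the furosemide list")
    return ace, fur


def bicar_trajectory(ind: IndividualParameters, fx: FixedEffects,
                     ace_doses=(), fur_doses=(), t_grid=None, *,
                     method: str = "exact",
                     ace_amount_fn=None, fur_amount_fn=None,
                     rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Bicarbonate concentration on ``t_grid`` (days, non-negative, increasing).

    ``method='exact'`` uses the integrating-factor solution (bolus
    trains only); ``method='rk'`` integrates with an adaptive
    Runge-Kutta scheme with dose times forced as breakpoints and the
    drug amount evaluated analytically. ``ace_amount_fn`` /
    ``fur_amount_fn`` override the bolus amount with an arbitrary
    function of time (e.g. a clamped constant) and force the RK path.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(t_grid < 0) or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be non-negative and increasing")
    ace, fur = _split_doses(ace_doses, fur_doses)
    if ace_amount_fn is not None or fur_amount_fn is not None:
        method = "rk"
    if method == "exact":
        t_max = max(t_grid[-1], 1e-9)
        bounds = engine.build_boundaries(
            np.concatenate([dose_times(ace), dose_times(fur)])
            if (ace or fur) else [], t_max,
        )
        ca = _boundary_amounts(ace, fx.half_life, bounds)
        cf = _boundary_amounts(fur, fx.fur_half_life, bounds)
        traj = engine.BatchTrajectory(
            bounds, ca[None, :], cf[None, :], [ind.bicar0_i], [ind.kout_i],
            emax=fx.emax, a50=fx.a50, fur50=fx.fur50,
            half_life=fx.half_life, fur_half_life=fx.fur_half_life,
        )
        return traj.at(np.zeros(t_grid.size, dtype=int), t_grid)
    if method != "rk":
        raise ValueError(f"unknown method {method!r}")
    return _bicar_rk(ind, fx, ace, fur, t_grid, ace_amount_fn, fur_amount_fn,
                     rtol, atol)


def _boundary_amounts(doses, half_life, bounds):
    if not doses:
        return np.zeros(bounds.size)
    return np.asarray(drug_amount(doses, half_life, bounds))


def _bicar_rk(ind, fx, ace, fur, t_grid, ace_fn, fur_fn, rtol, atol):
    kin = derive_kin(ind.bicar0_i, ind.kout_i)

    def amount(fn, doses, half_life, t):
        if fn is not None:
            return fn(t)
        return drug_amount(doses, half_life, t) if doses else 0.0

    def rhs(t, y):
        a = amount(ace_fn, ace, fx.half_life, t)
        f = amount(fur_fn, fur, fx.fur_half_life, t)
        stim_a = fx.emax * a / (a + fx.a50)
        stim_f = f / (f + fx.fur50)
        return [kin * (1.0 + stim_f) - ind.kout_i * (1.0 + stim_a) * y[0]]

    breakpoints = np.unique(np.concatenate([
        [0.0], dose_times(ace), dose_times(fur), [t_grid[-1]]]))
    breakpoints = breakpoints[breakpoints <= t_grid[-1] + 1e-12]
    out = np.empty_like(t_grid)
    y = ind.bicar0_i
    t_left = 0.0
    filled = 0
    pending0 = t_grid == 0.0
    out[pending0] = ind.bicar0_i
    filled = int(pending0.sum())
    for t_right in breakpoints[1:]:
        mask = (t_grid > t_left + 1e-15) & (t_grid <= t_right + 1e-15)
        t_eval = t_grid[mask]
        sol = solve_ivp(rhs, (t_left, t_right), [y], method="RK45",
                        t_eval=t_eval if t_eval.size else None,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"turnover ODE integration failed on [{t_left}, {t_right}]: "
                f"{sol.message}")
        if t_eval.size:
            out[mask] = sol.y[0]
        # re-integrate to the segment end for the next initial condition
        sol_end = solve_ivp(rhs, (t_left, t_right), [y], method="RK45",
                            rtol=rtol, atol=atol)
        if not sol_end.success:
            raise RuntimeError(
                f"turnover ODE integration failed on [{t_left}, {t_right}]: "
                f"{sol_end.message}")
        y = sol_end.y[0, -1]
        t_left = t_right
        filled += int(t_eval.size)
    if filled != t_grid.size:  # grid points beyond the last breakpoint
        raise RuntimeError("t_grid extends beyond the integration window")
    return out


@dataclass(frozen=True)
class Trajectory:
    """Deterministic solution of the full chain on a time grid."""

    times: np.ndarray
    drug_amount: np.ndarray
    bicar: np.ndarray
    mv: np.ndarray
    paco2: np.ndarray


def simulate_chain(ind: IndividualParameters, fx: FixedEffects, cov: Covariates,
                   ace_doses=(), fur_doses=(), t_grid=None,
                   method: str = "exact") -> Trajectory:
    """Evaluate drug amount, bicarbonate, MV and PaCO2 on a grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    bicar = bicar_trajectory(ind, fx, ace_doses, fur_doses, t_grid, method=method)
    mv = mv_from_bicar(ind, fx, cov, bicar)
    paco2 = paco2_from_mv(ind, mv, mv_baseline(ind, fx, cov))
    ace, _ = _split_doses(ace_doses, fur_doses)
    amt = np.asarray(drug_amount(ace, fx.half_life, t_grid)) if ace else np.zeros_like(t_grid)
    return Trajectory(times=t_grid, drug_amount=amt, bicar=np.asarray(bicar),
                      mv=np.asarray(mv), paco2=np.asarray(paco2))
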