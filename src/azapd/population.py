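"""Hierarchical layer: individual parameters and the observation model.

Individual parameters are log-normal around their covariate-adjusted
population values, theta_i = theta_cov * exp(eta) with eta ~ N(0, omega^2)
independently per parameter. Observations carry proportional residual
error, y = pred * (1 + eps), eps ~ N(0, sigma^2) — a constant
coefficient of variation. Simulated observations that fall non-positive
(vanishingly rare at the fitted sigmas) are resampled, since all three
observables are physiological positives.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import turnover
from .params import Covariates, FixedEffects, IndividualParameters, RandomEffects, ResidualError

# order of the random-effect components throughout the package
ETA_NAMES = ("bicar0", "kout", "mv0", "paco2_0", "pow_mv_paco2")

DVID_NAMES = ("BICAR", "MV", "PACO2")


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def individual_from_eta(fx: FixedEffects, cov: Covariates, eta) -> IndividualParameters:
    """Realise a subject's parameters from a 5-vector of random effects."""
    eta = np.asarray(eta, dtype=float)
    return IndividualParameters(
        bicar0_i=turnover.covariate_bicar0(fx.bicar0_pop, cov, fx) * np.exp(eta[0]),
        kout_i=fx.kout * np.exp(eta[1]),
        mv0_i=fx.mv0_pop * np.exp(eta[2]),
        paco2_0_i=fx.paco2_0_pop * np.exp(eta[3]),
        pow_mv_paco2_i=fx.pow_mv_paco2 * np.exp(eta[4]),
    )


def sample_individual(fx: FixedEffects, re: RandomEffects, cov: Covariates,
                      rng_seed) -> IndividualParameters:
    """Draw one subject's parameters (reproducible given the seed)."""
    rng = _as_rng(rng_seed)
    eta = rng.standard_normal(5) * re.as_array()
    return individual_from_eta(fx, cov, eta)


def observe(pred, sigma: float, rng_seed) -> np.ndarray | float:
    """Apply proportional residual error; non-positive draws are resampled."""
    rng = _as_rng(rng_seed)
    pred_arr = np.atleast_1d(np.asarray(pred, dtype=float))
    if np.any(pred_arr <= 0):
        raise ValueError("predictions must be strictly positive")
    y = pred_arr * (1.0 + sigma * rng.standard_normal(pred_arr.shape))
    for _ in range(100):
        bad = y <= 0
        if not np.any(bad):
            break
        y[bad] = pred_arr[bad] * (1.0 + sigma * rng.standard_normal(int(bad.sum())))
    else:  # pragma: no cover - requires sigma near or above 1
        raise RuntimeError("could not draw positive observations; sigma too large")
    return float(y[0]) if np.ndim(pred) == 0 else y


def _sigma_for(res: ResidualError, dvid: str) -> float:
    return {"BICAR": res.sigma_bicar, "MV": res.sigma_mv, "PACO2": res.sigma_paco2}[dvid]


def individual_loglik(subject, ind: IndividualParameters, fx: FixedEffects,
                      res: ResidualError) -> float:
    """Log-density of one subject's observations given individual parameters.

    Proportional error: y ~ N(pred, (sigma_dvid * pred)^2), summed over
    the subject's observations of all three types.
    """
    times = np.array([o.time for o in subject.observations], dtype=float)
    if times.size == 0:
        return 0.0
    ace = [d for d in subject.doses if d.drug.value == "ACZ"]
    fur = [d for d in subject.doses if d.drug.value == "FUR"]
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    bicar = turnover.bicar_trajectory(ind, fx, ace, fur, t_sorted)
    bicar_at = dict(zip(t_sorted, bicar))
    mv_base = turnover.mv_baseline(ind, fx, subject.covariates)
    total = 0.0
    for obs in subject.observations:
        b = bicar_at[obs.time]
        if obs.dvid.name == "BICAR":
            pred = b
        elif obs.dvid.name == "MV":
            pred = turnover.mv_from_bicar(ind, fx, subject.covariates, b)
        else:
            mv = turnover.mv_from_bicar(ind, fx, subject.covariates, b)
            pred = turnover.paco2_from_mv(ind, mv, mv_base)
        if pred <= 0:
            raise ValueError("non-positive model prediction")
        sd = _sigma_for(res, obs.dvid.name) * pred
        total += stats.norm.logpdf(obs.value, loc=pred, scale=sd)
    return float(total)
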