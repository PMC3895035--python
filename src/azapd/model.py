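"""Model and results objects for the acetazolamide pharmacodynamic model.

`AcetazolamidePD` is constructed from a longitudinal dataset and fitted
by SAEM; `SAEMResults` carries the population estimates, their relative
standard errors, empirical Bayes random effects, the marginal
log-likelihood (importance sampling) and AIC, and exposes diagnostics
and simulation. Typical use::

    model = AcetazolamidePD.from_csv("cohort.csv")
    res = model.fit()
    print(res.summary())
    npde = res.npde(n_sim=500, seed=1)
    sim = res.simulate_regimen(RegimenSpec(daily_dose=1000), n_subjects=10_000)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset, read_dataset
from .likelihood import loglik_importance, state_from_params
from .params import PopulationParameters, default_population
from .saem import SAEM, BatchData, CovariateModel, ETA_NAMES, SaemConfig, _Sampler


def simulate_observation_matrix(batch: BatchData, params: PopulationParameters,
                                n_sim: int, rng, include_residual: bool = True):
    """Simulate ``n_sim`` full-model replicates of every observation.

    Returns an (n_obs, n_sim) matrix: fresh random effects per subject
    and replicate, deterministic chain predictions at the observed
    times, and (optionally) proportional residual error with
    non-positive draws resampled.
    """
    state = state_from_params(params, batch.covmodel)
    sampler = _Sampler(batch, SaemConfig(), state["omega"] > 0, rng)
    mu = sampler.mu(state)
    omega = state["omega"]
    sigma = state["sigma"]
    n, m = batch.n, batch.m
    eta = rng.standard_normal((n_sim, n, 5)) * omega
    psi = np.exp(mu[None, :, :] + eta).reshape(n_sim * n, 5)
    from .engine import BatchTrajectory

    traj = BatchTrajectory(
        batch.boundaries,
        np.tile(batch.ca, (n_sim, 1)), np.tile(batch.cf, (n_sim, 1)),
        psi[:, 0], psi[:, 1],
        emax=batch.emax, a50=params.fixed.a50, fur50=params.fixed.fur50,
        half_life=batch.half_life, fur_half_life=batch.fur_half_life,
    )
    rows = (np.arange(n_sim)[:, None] * n + batch.obs_sub[None, :]).ravel()
    times = np.tile(batch.obs_time, n_sim)
    dvid = np.tile(batch.obs_dvid, n_sim)
    b = traj.at(rows, times)
    pred = np.empty(b.size)
    p_bm = params.fixed.pow_bicar_mv
    mask = dvid == 0
    pred[mask] = b[mask]
    mask = dvid == 1
    pred[mask] = psi[rows[mask], 2] * (batch.bicar_ref / b[mask]) ** p_bm
    mask = dvid == 2
    pred[mask] = psi[rows[mask], 3] * (
        b[mask] / psi[rows[mask], 0]) ** (p_bm * psi[rows[mask], 4])
    if not include_residual:
        return pred.reshape(n_sim, m).T
    y = pred * (1.0 + sigma[dvid] * rng.standard_normal(pred.size))
    for _ in range(100):
        bad = y <= 0
        if not bad.any():
            break
        y[bad] = pred[bad] * (1.0 + sigma[dvid[bad]] * rng.standard_normal(int(bad.sum())))
    return y.reshape(n_sim, m).T


class AcetazolamidePD:
    """Population pharmacodynamic model of acetazolamide.

    Parameters
    ----------
    dataset
        Longitudinal dosing/observation records (:class:`Dataset`).
    covariate_model
        Which covariates enter Bicar0 and MV0; defaults to the full
        published covariate model.
    init
        Initial parameter bundle; defaults to the published estimates.
    """

    def __init__(self, dataset: Dataset, covariate_model: CovariateModel | None = None,
                 init: PopulationParameters | None = None):
        self.dataset = dataset
        self.covariate_model = covariate_model or CovariateModel()
        self.init = init or default_population()
        self.batch = BatchData(dataset, self.init.fixed, self.covariate_model)

    @classmethod
    def from_csv(cls, path, time_unit: str = "day", **kwargs) -> "AcetazolamidePD":
        return cls(read_dataset(path, time_unit=time_unit), **kwargs)

    def fit(self, config: SaemConfig | None = None) -> "SAEMResults":
        """Estimate the population parameters by SAEM."""
        config = config or SaemConfig()
        raw = SAEM(self.batch, self.init, config).estimate()
        return SAEMResults(self, raw, config)

    def loglik(self, params: PopulationParameters | None = None, *,
               n_is: int = 1000, seed: int = 0, eta_mean=None, eta_sd=None) -> dict:
        """Marginal log-likelihood of ``params`` by importance sampling."""
        return loglik_importance(self.batch, params or self.init,
                                 eta_mean=eta_mean, eta_sd=eta_sd,
                                 n_is=n_is, seed=seed)

    def predictions(self, params: PopulationParameters, eta=None) -> np.ndarray:
        """Chain predictions at the observed times for given parameters."""
        state = state_from_params(params, self.covariate_model)
        sampler = _Sampler(self.batch, SaemConfig(), state["omega"] > 0,
                           np.random.default_rng(0))
        mu = sampler.mu(state)
        eta = np.zeros((self.batch.n, 5)) if eta is None else np.asarray(eta)
        _, _, pred = sampler.subject_loglik(np.exp(mu + eta), state["phi"],
                                            state["sigma"])
        return pred


class SAEMResults:
    """Estimates, uncertainties and diagnostics of a SAEM fit."""

    def __init__(self, model: AcetazolamidePD, raw: dict, config: SaemConfig):
        self.model = model
        self.params: PopulationParameters = raw["params"]
        self.rse: dict | None = raw["rse"]
        self.trace: pd.DataFrame = raw["trace"]
        self.eta_mean: np.ndarray = raw["eta_mean"]
        self.eta_sd: np.ndarray = raw["eta_sd"]
        self.n_free: int = raw["n_free"]
        self.config = config
        self._llf_cache: dict | None = None

    # -- likelihood ------------------------------------------------------
    def _loglik(self):
        if self._llf_cache is None:
            self._llf_cache = self.model.loglik(
                self.params, n_is=1000, seed=self.config.seed + 104729,
                eta_mean=self.eta_mean, eta_sd=self.eta_sd)
        return self._llf_cache

    @property
    def llf(self) -> float:
        """Marginal log-likelihood (importance sampling)."""
        return self._loglik()["loglik"]

    @property
    def llf_se(self) -> float:
        return self._loglik()["se"]

    @property
    def aic(self) -> float:
        """Akaike information criterion, -2 LL + 2 k."""
        return -2.0 * self.llf + 2.0 * self.n_free

    # -- diagnostics -----------------------------------------------------
    def shrinkage(self) -> dict:
        """Eta-shrinkage 1 - sd(eta)/omega per random effect."""
        from .diagnostics import shrinkage

        omega = self.params.random.as_array()
        out = {}
        for j, nm in enumerate(ETA_NAMES):
            if omega[j] > 0:
                out[nm] = shrinkage(self.eta_mean[:, j], omega[j])
        return out

    def npde(self, n_sim: int = 500, seed: int = 0):
        from .diagnostics import compute_npde

        return compute_npde(self.model.batch, self.params, n_sim=n_sim, seed=seed)

    def gof(self):
        from .diagnostics import gof_tables

        return gof_tables(self)

    # -- simulation ------------------------------------------------------
    def simulate_observations(self, n_sim: int = 1, seed: int = 0,
                              include_residual: bool = True) -> np.ndarray:
        """Replicate observation matrix under the fitted model."""
        return simulate_observation_matrix(
            self.model.batch, self.params, n_sim,
            np.random.default_rng(seed), include_residual=include_residual)

    def simulate_regimen(self, regimen, n_subjects: int = 10_000, seed: int = 0,
                         **kwargs) -> pd.DataFrame:
        from .regimen import simulate_regimen

        return simulate_regimen(self.params, regimen, n_subjects=n_subjects,
                                seed=seed, **kwargs)

    # -- reporting -------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        fx = self.params.fixed
        om = self.params.random
        res = self.params.residual
        rse = self.rse or {}

        def row(name, est, bsv=None, bsv_key=None):
            return {
                "parameter": name, "estimate": est,
                "rse_pct": rse.get(name, np.nan),
                "bsv_omega": bsv if bsv is not None else np.nan,
                "bsv_rse_pct": rse.get(bsv_key, np.nan) if bsv_key else np.nan,
            }

        rows = [
            row("half_life", fx.half_life), row("emax", fx.emax),
            row("bicar0_pop", fx.bicar0_pop, om.omega_bicar0, "omega_bicar0"),
            row("beta_saps", fx.beta_saps),
            row("cortico_mult", fx.cortico_mult),
            row("beta_chloride", fx.beta_chloride),
            row("kout", fx.kout, om.omega_kout, "omega_kout"),
            row("a50", fx.a50), row("fur50", fx.fur50),
            row("mv0_pop", fx.mv0_pop, om.omega_mv0, "omega_mv0"),
            row("va_mult", fx.va_mult), row("female_mult", fx.female_mult),
            row("pow_bicar_mv", fx.pow_bicar_mv),
            row("paco2_0_pop", fx.paco2_0_pop, om.omega_paco2_0, "omega_paco2_0"),
            row("pow_mv_paco2", fx.pow_mv_paco2, om.omega_pow_mv_paco2,
                "omega_pow_mv_paco2"),
            row("sigma_bicar", res.sigma_bicar),
            row("sigma_mv", res.sigma_mv),
            row("sigma_paco2", res.sigma_paco2),
        ]
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [
            "Acetazolamide population pharmacodynamics - SAEM fit",
            f"subjects: {self.model.batch.n}   observations: {self.model.batch.m}"
            f"   free parameters: {self.n_free}",
            "",
            frame.to_string(float_format=lambda v: f"{v:.4g}", na_rep="-"),
        ]
        if self._llf_cache is not None:
            lines.insert(2, f"loglik: {self.llf:.2f} (MC se {self.llf_se:.2f})"
                            f"   AIC: {self.aic:.2f}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<SAEMResults: {self.model.batch.n} subjects, "
                f"{self.n_free} free parameters>")


def compare_models(res_a: SAEMResults, res_b: SAEMResults) -> dict:
    """AIC difference and likelihood-ratio test of nested fits.

    ``res_b`` must nest ``res_a`` (its covariate model contains A's
    terms) for the LRT to be valid; otherwise only the AIC comparison
    is returned with a warning.
    """
    delta_aic = res_b.aic - res_a.aic
    cm_a, cm_b = res_a.model.covariate_model, res_b.model.covariate_model
    pairs_a = {("bicar0", c) for c in cm_a.bicar0} | {("mv0", c) for c in cm_a.mv0}
    pairs_b = {("bicar0", c) for c in cm_b.bicar0} | {("mv0", c) for c in cm_b.mv0}
    nested = pairs_a <= pairs_b and res_b.n_free >= res_a.n_free
    if not nested:
        warnings.warn("models are not nested; returning AIC comparison only")
        return {"delta_aic": delta_aic, "lrt": None, "df": None, "p_value": None}
    df = res_b.n_free - res_a.n_free
    lrt = max(-2.0 * (res_a.llf - res_b.llf), 0.0)
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    if df == 0 and lrt == 0.0:
        p = 1.0
    return {"delta_aic": delta_aic, "lrt": lrt, "df": df, "p_value": p}


def select_covariates(dataset: Dataset, candidates, *,
                      base: CovariateModel | None = None,
                      init: PopulationParameters | None = None,
                      config: SaemConfig | None = None) -> dict:
    """Forward covariate selection by AIC.

    ``candidates`` is an ordered list of ``(parameter, covariate)``
    pairs, e.g. ``[("bicar0", "chloride"), ("mv0", "female")]``. At
    each round every remaining candidate is added to the current model,
    the one with the largest AIC improvement is kept if its AIC
    decreases, and the search stops otherwise.
    """
    base = base or CovariateModel(bicar0=(), mv0=())
    config = config or SaemConfig()
    current = base
    current_res = AcetazolamidePD(dataset, current, init=init).fit(config)
    report = []
    remaining = list(candidates)
    while remaining:
        trials = []
        for param, cov in remaining:
            cm = current.with_added(param, cov)
            res = AcetazolamidePD(dataset, cm, init=init).fit(config)
            trials.append(((param, cov), cm, res))
            report.append({"parameter": param, "covariate": cov,
                           "aic": res.aic, "ref_aic": current_res.aic,
                           "delta_aic": res.aic - current_res.aic})
        best = min(trials, key=lambda t: t[2].aic)
        if best[2].aic < current_res.aic:
            current, current_res = best[1], best[2]
            remaining.remove(best[0])
            report[-len(trials) + trials.index(best)]["kept"] = True
        else:
            break
    for entry in report:
        entry.setdefault("kept", False)
    return {"model": current, "results": current_res,
            "report": pd.DataFrame(report)}
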