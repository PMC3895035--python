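"""Model diagnostics: NPDE, location/scale tests, shrinkage, GOF tables.

Normalised prediction distribution errors (NPDE) are rank-based
residuals computed against Monte-Carlo simulations of the full model:
each subject's observation vector and its simulated replicates are
decorrelated with the inverse Cholesky factor of the empirical
simulated covariance, the decorrelated observation is ranked among its
decorrelated replicates, and the rank quantile is mapped through the
standard-normal inverse CDF. Under a correct model the NPDE are
i.i.d. N(0, 1): their mean is tested with a Wilcoxon signed-rank test
and their variance with a chi-square variance test against 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .model import simulate_observation_matrix
from .params import PopulationParameters
from .saem import BatchData

DVID_LABELS = ("BICAR", "MV", "PACO2")


def shrinkage(etas, omega: float) -> float:
    """Eta-shrinkage, 1 - sd(eta)/omega.

    Near 1 when the data carry almost no individual information (the
    empirical Bayes estimates collapse to the population value), near 0
    for rich individual data.
    """
    etas = np.asarray(etas, dtype=float)
    if omega <= 0:
        raise ValueError("omega must be strictly positive")
    if etas.size < 2:
        raise ValueError("at least two subjects are required")
    return float(1.0 - etas.std(ddof=1) / omega)


def variance_test(values, ref_var: float = 1.0) -> float:
    """Two-sided chi-square test of Var(values) against ``ref_var``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    statistic = (n - 1) * values.var(ddof=1) / ref_var
    cdf = stats.chi2.cdf(statistic, n - 1)
    return float(2.0 * min(cdf, 1.0 - cdf))


def npde_tests(values) -> dict:
    """Location, scale and normality tests of an NPDE sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 npde values")
    if np.ptp(values) == 0:
        raise ValueError("constant npde values")
    wil = float(stats.wilcoxon(values).pvalue)
    var_p = variance_test(values)
    if values.size <= 5000:
        norm_p = float(stats.shapiro(values).pvalue)
    else:  # pragma: no cover - large-sample fallback
        norm_p = float(stats.kstest(values, "norm").pvalue)
    return {"wilcoxon_p": wil, "fisher_var_p": var_p, "normality_p": norm_p}


@dataclass
class NPDEResult:
    """Per-observation NPDE values plus calibration tests per data type."""

    table: pd.DataFrame          # subject, time, dvid, observed, npde, pd
    tests: dict                  # dvid -> {wilcoxon_p, fisher_var_p, normality_p}
    n_sim: int
    seed: int

    @property
    def npde(self) -> np.ndarray:
        return self.table["npde"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_npde(batch: BatchData, params: PopulationParameters, *,
                 n_sim: int = 500, seed: int = 0, ridge: float = 1e-8) -> NPDEResult:
    """NPDE of the observed data against ``n_sim`` model simulations.

    The decorrelation step uses the Cholesky factor of each subject's
    empirical simulated covariance; a singular covariance is ridge-
    regularised with a warning. Rank ties are broken by the
    (rank + U(0,1))/(n_sim + 1) convention and the quantile is clipped
    away from 0 and 1 to keep the normal inverse finite.
    """
    if n_sim < 50:
        raise ValueError("n_sim must be at least 50")
    rng = np.random.default_rng(seed)
    sims = simulate_observation_matrix(batch, params, n_sim, rng)  # (m, n_sim)
    y = batch.obs_y
    npde = np.empty(batch.m)
    pd_vals = np.empty(batch.m)
    clip_lo = 1.0 / (2.0 * (n_sim + 1))
    for i in range(batch.n):
        idx = np.where(batch.obs_sub == i)[0]
        s = sims[idx]                      # (L, n_sim)
        mean = s.mean(axis=1)
        cov = np.cov(s) if idx.size > 1 else np.array([[s.var(ddof=1)]])
        cov = np.atleast_2d(cov)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular simulated covariance for subject index {i}; "
                          "ridge-regularised")
            chol = np.linalg.cholesky(cov + ridge * np.trace(cov)
                                      / idx.size * np.eye(idx.size))
        y_dec = solve_triangular(chol, y[idx] - mean, lower=True)
        # finite-simulation correction: whitening with a covariance
        # estimated from the n_sim replicates alone inflates the
        # observation's variance by (1 + 1/n)(n-1)/(n-L-2) relative to
        # the whitened cloud (Wishart inverse moment plus the estimated
        # mean); deflate before ranking so the pd are uniform
        L = idx.size
        c2 = (1.0 + 1.0 / n_sim) * (n_sim - 1.0) / max(n_sim - L - 2.0, 1.0)
        y_dec = y_dec / np.sqrt(c2)
        s_dec = solve_triangular(chol, s - mean[:, None], lower=True)
        rank = (s_dec < y_dec[:, None]).sum(axis=1)
        u = rng.random(idx.size)
        p = np.clip((rank + u) / (n_sim + 1.0), clip_lo, 1.0 - clip_lo)
        pd_vals[idx] = p
        npde[idx] = stats.norm.ppf(p)
    subject_ids = np.array([s.id for s in batch.dataset])
    table = pd.DataFrame({
        "subject": subject_ids[batch.obs_sub],
        "time": batch.obs_time,
        "dvid": [DVID_LABELS[d] for d in batch.obs_dvid],
        "observed": y,
        "pd": pd_vals,
        "npde": npde,
    })
    tests = {}
    for d, label in enumerate(DVID_LABELS):
        mask = batch.obs_dvid == d
        if mask.sum() >= 10:
            tests[label] = npde_tests(npde[mask])
    tests["ALL"] = npde_tests(npde)
    return NPDEResult(table=table, tests=tests, n_sim=n_sim, seed=seed)


def gof_tables(results) -> dict:
    """Observed vs population- and individual-predicted values per type.

    Returns the aligned table and, per observation type, the
    least-squares slope of observed on individual-predicted through the
    origin (1 for a perfect identity-line fit).
    """
    model = results.model
    batch = model.batch
    pred_pop = model.predictions(results.params)
    pred_ind = model.predictions(results.params, eta=results.eta_mean)
    subject_ids = np.array([s.id for s in batch.dataset])
    table = pd.DataFrame({
        "subject": subject_ids[batch.obs_sub],
        "time": batch.obs_time,
        "dvid": [DVID_LABELS[d] for d in batch.obs_dvid],
        "observed": batch.obs_y,
        "pred_pop": pred_pop,
        "pred_ind": pred_ind,
    })
    slopes = {}
    for d, label in enumerate(DVID_LABELS):
        mask = batch.obs_dvid == d
        if mask.any():
            o, p = batch.obs_y[mask], pred_ind[mask]
            slopes[label] = float((o * p).sum() / (p * p).sum())
    return {"table": table, "slopes": slopes}
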