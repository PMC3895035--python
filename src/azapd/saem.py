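"""Stochastic-approximation EM (SAEM) with per-subject MCMC.

Maximum-likelihood estimation for the nonlinear mixed-effects model
without linearisation: the E-step runs a Metropolis random walk on each
subject's random-effect vector targeting its conditional posterior; the
stochastic-approximation step smooths the complete-data sufficient
statistics with gain 1 during burn-in and k^-a afterwards; the M-step
is closed form for everything that is linear on the log scale
(population medians, covariate coefficients, omegas, sigmas). The
remaining structural parameters without between-subject variability
(A50, furosemide F50 and the bicarbonate->MV exponent) are estimated
with the annealed artificial-variability device: they run in their own
Metropolis chain against the full-cohort likelihood with a Gaussian
prior of slowly shrinking width around the current population value,
and the population value tracks the chain by stochastic approximation.

Individual parameters are log-normal: log psi_i = X_i theta + eta_i,
eta_i ~ N(0, diag(omega^2)). On the log scale every covariate
relationship in the model is exactly linear, which is what makes the
closed-form M-step available:

    log Bicar0_i = log Bicar0_pop + beta_saps*log(SAPS/50)
                   + beta_chl*log(Cl/100) + cort_i*log(cortico_mult) + eta1
    log MVscale_i = log MV0_pop + va_i*log(va_mult) + fem_i*log(female_mult) + eta3

Internally ``psi[:, 2]`` therefore *includes* the mode/sex multipliers;
the public ``IndividualParameters.mv0_i`` convention (multipliers
applied in the MV link) divides them back out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import engine
from .dataset import Dataset
from .kinetics import Drug, drug_amount
from .params import (
    FixedEffects,
    PopulationParameters,
    RandomEffects,
    ResidualError,
)

ETA_NAMES = ("bicar0", "kout", "mv0", "paco2_0", "pow_mv_paco2")
_LOG_2PI = float(np.log(2 * np.pi))


@dataclass(frozen=True)
class CovariateModel:
    """Which covariates enter which structural parameter."""

    bicar0: tuple = ("saps2", "chloride", "corticosteroid")
    mv0: tuple = ("volume_assist", "female")

    def with_added(self, param: str, cov: str) -> "CovariateModel":
        current = getattr(self, param)
        if cov in current:
            return self
        return replace(self, **{param: current + (cov,)})

    def n_covariate_terms(self) -> int:
        return len(self.bicar0) + len(self.mv0)


@dataclass(frozen=True)
class SaemConfig:
    n_burn: int = 150
    n_smooth: int = 300
    step_exponent: float = 0.7   # gain k^-a during the smoothing phase
    n_mcmc: int = 4              # MCMC transitions per SAEM iteration
    proposal_scale: float = 0.4
    accept_target: float = 0.35  # adapted toward during burn-in only
    seed: int = 0
    compute_rse: bool = True
    n_post_samples: int = 100    # posterior draws for eta means / FIM / IS proposal
    omega_sampling_floor: float = 0.005
    n_phi_mcmc: int = 2          # transitions of the structural-parameter chain
    phi_step0: float = 0.15      # initial artificial SD of the structural chain
    phi_step_floor: float = 0.05  # annealing floor of that SD

    def __post_init__(self):
        if self.n_burn < 0 or self.n_smooth < 0:
            raise ValueError("iteration counts must be non-negative")
        if not 0.5 < self.step_exponent <= 1.0:
            raise ValueError("step_exponent must lie in (0.5, 1]")
        if self.n_mcmc < 1:
            raise ValueError("n_mcmc must be >= 1")


class BatchData:
    """Flat, vectorisable view of a dataset for one structural setup."""

    def __init__(self, dataset: Dataset, fx: FixedEffects, covmodel: CovariateModel):
        self.dataset = dataset
        self.covmodel = covmodel
        n = len(dataset)
        if n == 0:
            raise ValueError("dataset has no subjects")
        for s in dataset:
            if not s.observations:
                raise ValueError(f"subject {s.id} has no observations")
        obs_sub, obs_time, obs_dvid, obs_y = [], [], [], []
        all_dose_times = [0.0]
        for i, s in enumerate(dataset):
            for o in s.observations:
                obs_sub.append(i)
                obs_time.append(o.time)
                obs_dvid.append(("BICAR", "MV", "PACO2").index(o.dvid.value))
                obs_y.append(o.value)
            all_dose_times.extend(d.time for d in s.doses)
        self.obs_sub = np.asarray(obs_sub, dtype=int)
        self.obs_time = np.asarray(obs_time, dtype=float)
        self.obs_dvid = np.asarray(obs_dvid, dtype=int)
        self.obs_y = np.asarray(obs_y, dtype=float)
        self.n = n
        self.m = self.obs_y.size
        self.n_obs_dvid = np.bincount(self.obs_dvid, minlength=3)
        t_max = max(self.obs_time.max(), max(all_dose_times)) + 1e-9
        self.boundaries = engine.build_boundaries(np.unique(all_dose_times), t_max)
        self.ca = np.zeros((n, self.boundaries.size))
        self.cf = np.zeros((n, self.boundaries.size))
        for i, s in enumerate(dataset):
            ace = s.doses_for(Drug.ACETAZOLAMIDE)
            fur = s.doses_for(Drug.FUROSEMIDE)
            if ace:
                self.ca[i] = drug_amount(ace, fx.half_life, self.boundaries)
            if fur:
                self.cf[i] = drug_amount(fur, fx.fur_half_life, self.boundaries)
        self.any_fur = bool(np.any(self.cf > 0))
        cov = [s.covariates for s in dataset]
        self.log_saps = np.log([c.saps2 / 50.0 for c in cov])
        self.log_chl = np.log([c.chloride / 100.0 for c in cov])
        self.cort = np.array([float(c.corticosteroid) for c in cov])
        self.female = np.array([float(c.female) for c in cov])
        self.va = np.array([float(c.volume_assist) for c in cov])
        self.X_bicar = self._design("bicar0")
        self.X_mv = self._design("mv0")
        self.half_life = fx.half_life
        self.fur_half_life = fx.fur_half_life
        self.emax = fx.emax
        self.bicar_ref = fx.bicar_ref

    _COLUMNS = {
        ("bicar0", "saps2"): "log_saps",
        ("bicar0", "chloride"): "log_chl",
        ("bicar0", "corticosteroid"): "cort",
        ("mv0", "volume_assist"): "va",
        ("mv0", "female"): "female",
    }

    def _design(self, param: str) -> np.ndarray:
        cols = [np.ones(self.n)]
        for cov_name in getattr(self.covmodel, param):
            key = (param, cov_name)
            if key not in self._COLUMNS:
                raise ValueError(f"unknown covariate {cov_name!r} for {param}")
            cols.append(np.asarray(getattr(self, self._COLUMNS[key]), dtype=float))
        return np.column_stack(cols)


def _theta_vectors(fx: FixedEffects, covmodel: CovariateModel):
    """Regression coefficients per block, in design-matrix column order."""
    coef_map = {
        ("bicar0", "saps2"): fx.beta_saps,
        ("bicar0", "chloride"): fx.beta_chloride,
        ("bicar0", "corticosteroid"): np.log(fx.cortico_mult),
        ("mv0", "volume_assist"): np.log(fx.va_mult),
        ("mv0", "female"): np.log(fx.female_mult),
    }
    coef_b = [np.log(fx.bicar0_pop)] + [coef_map[("bicar0", c)] for c in covmodel.bicar0]
    coef_m = [np.log(fx.mv0_pop)] + [coef_map[("mv0", c)] for c in covmodel.mv0]
    return (np.asarray(coef_b), np.asarray(coef_m),
            np.log(fx.kout), np.log(fx.paco2_0_pop), np.log(fx.pow_mv_paco2))


def _fx_from_state(state, template: FixedEffects, covmodel: CovariateModel) -> FixedEffects:
    coef_b, coef_m = state["coef_b"], state["coef_m"]
    updates = dict(
        bicar0_pop=float(np.exp(coef_b[0])),
        mv0_pop=float(np.exp(coef_m[0])),
        kout=float(np.exp(state["log_kout"])),
        paco2_0_pop=float(np.exp(state["log_paco2_0"])),
        pow_mv_paco2=float(np.exp(state["log_pow_mv_paco2"])),
        a50=float(np.exp(state["phi"][0])),
        fur50=float(np.exp(state["phi"][1])),
        pow_bicar_mv=float(np.exp(state["phi"][2])),
        beta_saps=0.0, beta_chloride=0.0, cortico_mult=1.0,
        va_mult=1.0, female_mult=1.0,
    )
    for j, cov_name in enumerate(covmodel.bicar0, start=1):
        value = float(coef_b[j])
        if cov_name == "saps2":
            updates["beta_saps"] = value
        elif cov_name == "chloride":
            updates["beta_chloride"] = value
        else:
            updates["cortico_mult"] = float(np.exp(value))
    for j, cov_name in enumerate(covmodel.mv0, start=1):
        value = float(np.exp(coef_m[j]))
        if cov_name == "volume_assist":
            updates["va_mult"] = value
        else:
            updates["female_mult"] = value
    return replace(template, **updates)


class _Sampler:
    """Vectorised Metropolis random walk over all subjects at once.

    The chain state is the individual log-parameter matrix ``z``
    (log psi), not the deviation eta: individuals therefore stay
    anchored to their data when the M-step moves the population means,
    which removes the feedback random walk a sticky eta chain would
    impose on weakly informed coefficients.
    """

    BLOCKS = ((0, 1), (2, 3, 4))  # (affects the ODE) / (algebraic only)

    def __init__(self, batch: BatchData, config: SaemConfig, eta_free, rng):
        self.batch = batch
        self.config = config
        self.eta_free = np.asarray(eta_free, dtype=bool)
        self.rng = rng
        self.z = None  # individual log-parameters, set on first refresh
        self.scale = np.full((batch.n, len(self.BLOCKS)), config.proposal_scale)
        self.b_obs = None
        self.ll = None  # per-subject observation loglik

    @staticmethod
    def _phi_of(state):
        return state.get("phi_sample", state["phi"])

    # -- model evaluation ------------------------------------------------
    def mu(self, state):
        batch = self.batch
        mu = np.empty((batch.n, 5))
        mu[:, 0] = batch.X_bicar @ state["coef_b"]
        mu[:, 1] = state["log_kout"]
        mu[:, 2] = batch.X_mv @ state["coef_m"]
        mu[:, 3] = state["log_paco2_0"]
        mu[:, 4] = state["log_pow_mv_paco2"]
        return mu

    def _b_obs_for(self, psi, phi):
        batch = self.batch
        traj = engine.BatchTrajectory(
            batch.boundaries, batch.ca, batch.cf, psi[:, 0], psi[:, 1],
            emax=batch.emax, a50=np.exp(phi[0]), fur50=np.exp(phi[1]),
            half_life=batch.half_life, fur_half_life=batch.fur_half_life,
        )
        return traj.at(batch.obs_sub, batch.obs_time)

    def _predict(self, psi, phi, b_obs):
        batch = self.batch
        r = batch.obs_sub
        pred = np.empty(batch.m)
        p_bm = np.exp(phi[2])
        mask = batch.obs_dvid == 0
        pred[mask] = b_obs[mask]
        mask = batch.obs_dvid == 1
        pred[mask] = psi[r[mask], 2] * (batch.bicar_ref / b_obs[mask]) ** p_bm
        mask = batch.obs_dvid == 2
        pred[mask] = psi[r[mask], 3] * (
            b_obs[mask] / psi[r[mask], 0]) ** (p_bm * psi[r[mask], 4])
        return pred

    def subject_loglik(self, psi, phi, sigma, b_obs=None):
        batch = self.batch
        if b_obs is None:
            b_obs = self._b_obs_for(psi, phi)
        pred = self._predict(psi, phi, b_obs)
        sd = sigma[batch.obs_dvid] * pred
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            contrib = (-np.log(sd) - 0.5 * _LOG_2PI
                       - 0.5 * ((batch.obs_y - pred) / sd) ** 2)
        # extreme proposals can underflow predictions to zero; give them
        # zero posterior mass instead of propagating NaN
        contrib = np.where(np.isfinite(contrib), contrib, -np.inf)
        return np.bincount(batch.obs_sub, weights=contrib, minlength=batch.n), b_obs, pred

    # -- MCMC ------------------------------------------------------------
    def refresh(self, state):
        mu = self.mu(state)
        if self.z is None:
            self.z = mu.copy()
        # parameters without a random effect track the population value
        self.z[:, ~self.eta_free] = mu[:, ~self.eta_free]
        self.ll, self.b_obs, _ = self.subject_loglik(
            np.exp(self.z), self._phi_of(state), state["sigma"])
        return mu

    def transition(self, state, omega_samp, adapt: bool):
        """One full sweep: ODE block then algebraic block."""
        mu = self.mu(state)
        phi, sigma = self._phi_of(state), state["sigma"]
        for bi, block in enumerate(self.BLOCKS):
            dims = [d for d in block if self.eta_free[d]]
            if not dims:
                continue
            z_new = self.z.copy()
            step = self.scale[:, bi][:, None] * omega_samp[dims]
            z_new[:, dims] = self.z[:, dims] + step * self.rng.standard_normal(
                (self.batch.n, len(dims)))
            psi_new = np.exp(z_new)
            if bi == 0:
                ll_new, b_new, _ = self.subject_loglik(psi_new, phi, sigma)
            else:
                ll_new, b_new, _ = self.subject_loglik(
                    psi_new, phi, sigma, b_obs=self.b_obs)
            dprior = -0.5 * (
                ((z_new[:, dims] - mu[:, dims]) / omega_samp[dims]) ** 2
                - ((self.z[:, dims] - mu[:, dims]) / omega_samp[dims]) ** 2
            ).sum(axis=1)
            log_alpha = ll_new - self.ll + dprior
            accept = np.log(self.rng.random(self.batch.n)) < log_alpha
            self.z[accept] = z_new[accept]
            self.ll = np.where(accept, ll_new, self.ll)
            if bi == 0:
                self.b_obs = np.where(accept[self.batch.obs_sub], b_new, self.b_obs)
            if adapt:
                self.scale[:, bi] *= np.exp(
                    0.4 * (accept.astype(float) - self.config.accept_target))
                np.clip(self.scale[:, bi], 0.01, 10.0, out=self.scale[:, bi])
        return mu


class SAEM:
    """Run SAEM on a :class:`BatchData`; returns raw state + traces."""

    def __init__(self, batch: BatchData, init: PopulationParameters,
                 config: SaemConfig):
        self.batch = batch
        self.config = config
        self.init = init
        mask = set(init.fixed_mask)
        unsupported = mask - {"emax", "half_life", "fur_half_life", "bicar_ref",
                              "a50", "fur50", "pow_bicar_mv"}
        if unsupported:
            raise ValueError(
                f"fixed_mask entries not supported by the estimator: {sorted(unsupported)}")
        free_names = []
        for name in ("a50", "fur50", "pow_bicar_mv"):
            if name in mask:
                continue
            if name == "fur50" and not batch.any_fur:
                continue  # no furosemide in the data: parameter not informed
            free_names.append(name)
        self.phi_free = [("a50", "fur50", "pow_bicar_mv").index(nm) for nm in free_names]
        omega0 = init.random.as_array()
        self.eta_free = omega0 > 0
        if not (self.phi_free or self.eta_free.any()):
            raise ValueError("all parameters are fixed; nothing to estimate")
        self.n_free = (
            5  # population medians
            + batch.covmodel.n_covariate_terms()
            + len(self.phi_free)
            + int(self.eta_free.sum())
            + 3  # residual sigmas
        )

    def initial_state(self):
        fx = self.init.fixed
        coef_b, coef_m, log_kout, log_paco2, log_pow = _theta_vectors(
            fx, self.batch.covmodel)
        return {
            "coef_b": coef_b, "coef_m": coef_m,
            "log_kout": log_kout, "log_paco2_0": log_paco2,
            "log_pow_mv_paco2": log_pow,
            "phi": np.log([fx.a50, fx.fur50, fx.pow_bicar_mv]),
            "phi_sample": np.log([fx.a50, fx.fur50, fx.pow_bicar_mv]),
            "omega": self.init.random.as_array().copy(),
            "sigma": np.array([
                self.init.residual.sigma_bicar,
                self.init.residual.sigma_mv,
                self.init.residual.sigma_paco2,
            ]),
        }

    def run(self):
        config = self.config
        batch = self.batch
        rng = np.random.default_rng(config.seed)
        state = self.initial_state()
        sampler = _Sampler(batch, config, self.eta_free, rng)
        sampler.refresh(state)
        s_z = np.zeros((batch.n, 5))
        s_z2 = np.zeros((batch.n, 5))
        s_sig = np.zeros(3)
        trace_rows = []
        n_total = config.n_burn + config.n_smooth
        for k in range(1, n_total + 1):
            burn = k <= config.n_burn
            gamma = 1.0 if burn else (k - config.n_burn) ** (-config.step_exponent)
            # annealed artificial SD of the structural-parameter chain
            s_phi = config.phi_step0 if burn else max(
                config.phi_step0 * (k - config.n_burn) ** (-config.step_exponent / 2),
                config.phi_step_floor)
            # keep exploration alive while gain is 1, then release the floor
            floor = max(config.omega_sampling_floor, 0.05) if burn \
                else config.omega_sampling_floor
            omega_samp = np.maximum(state["omega"], floor)
            # average the sufficient statistics over the within-iteration
            # sweeps: same fixed point, lower stochastic-approximation noise
            z_acc = np.zeros_like(s_z)
            z2_acc = np.zeros_like(s_z2)
            sig_acc = np.zeros(3)
            for _ in range(config.n_mcmc):
                mu = sampler.transition(state, omega_samp, adapt=burn)
                if self.phi_free:
                    # extra burn-in transitions: the cohort likelihood is
                    # sharp, so the chain needs many small accepted moves
                    # to traverse the (kout, A50) ridge
                    for _ in range(config.n_phi_mcmc * (3 if burn else 1)):
                        # the structural chain keeps adapting its scale:
                        # its target narrows as s_phi anneals
                        self._phi_transition(state, sampler, mu, s_phi, rng,
                                             adapt=True)
                z_acc += sampler.z
                z2_acc += sampler.z ** 2
                _, _, pred = sampler.subject_loglik(
                    np.exp(sampler.z), state["phi_sample"], state["sigma"],
                    b_obs=sampler.b_obs)
                res2 = ((batch.obs_y - pred) / pred) ** 2
                sig_acc += np.array([
                    res2[batch.obs_dvid == d].sum() for d in range(3)])
            s_z += gamma * (z_acc / config.n_mcmc - s_z)
            s_z2 += gamma * (z2_acc / config.n_mcmc - s_z2)
            s_sig += gamma * (sig_acc / config.n_mcmc - s_sig)
            self._m_step(state, s_z, s_z2, s_sig, gamma)
            sampler.refresh(state)
            trace_rows.append(self._trace_row(state, k, burn))
        trace = pd.DataFrame(trace_rows)
        state["phi_sample"] = state["phi"].copy()
        post = self._posterior_pass(state, sampler, rng)
        return state, sampler, trace, post

    def _phi_transition(self, state, sampler, mu, s_phi, rng, adapt):
        """Metropolis step for (A50, F50, BICAR.MV power) on the log scale.

        The chain targets the product of all subjects' observation
        likelihoods with an artificial Gaussian prior of SD ``s_phi``
        centred at the current population value; the SA step then pulls
        the population value toward the sampled chain. The prior SD is
        held constant during burn-in and annealed during smoothing,
        which lets the chain climb likelihood ridges early and pins it
        down as the gain decreases.
        """
        free = self.phi_free
        phi = state["phi_sample"]
        prop = phi.copy()
        prop[free] = phi[free] + self.phi_scale * s_phi * rng.standard_normal(len(free))
        if np.any(prop[free] < self._PHI_LO[free]) or np.any(
                prop[free] > self._PHI_HI[free]):
            accept = False
        else:
            psi = np.exp(sampler.z)
            ll_new, b_new, _ = sampler.subject_loglik(psi, prop, state["sigma"])
            centre = state["phi"][free]
            dprior = -0.5 * (((prop[free] - centre) / s_phi) ** 2
                             - ((phi[free] - centre) / s_phi) ** 2).sum()
            log_alpha = float(ll_new.sum() - sampler.ll.sum()) + dprior
            accept = np.log(rng.random()) < log_alpha
            if accept:
                state["phi_sample"] = prop
                sampler.ll = ll_new
                sampler.b_obs = b_new
        if adapt:
            self.phi_scale *= np.exp(0.3 * (float(accept) - self.config.accept_target))
            self.phi_scale = float(np.clip(self.phi_scale, 0.02, 5.0))

    def _m_step(self, state, s_z, s_z2, s_sig, gamma):
        batch = self.batch
        # closed-form blocks (log-linear): OLS on SA-averaged log psi
        specs = [
            ("coef_b", batch.X_bicar, 0), ("log_kout", None, 1),
            ("coef_m", batch.X_mv, 2), ("log_paco2_0", None, 3),
            ("log_pow_mv_paco2", None, 4),
        ]
        omega2 = np.empty(5)
        for name, X, j in specs:
            if X is None:
                mu_j = float(np.mean(s_z[:, j]))
                state[name] = mu_j
                mu_vec = mu_j
            else:
                coef, *_ = np.linalg.lstsq(X, s_z[:, j], rcond=None)
                state[name] = coef
                mu_vec = X @ coef
            omega2[j] = np.mean(s_z2[:, j] - 2 * mu_vec * s_z[:, j] + mu_vec ** 2)
        state["omega"] = np.sqrt(np.maximum(omega2, 1e-10)) * self.eta_free
        state["sigma"] = np.sqrt(np.maximum(s_sig / batch.n_obs_dvid, 1e-10))
        if self.phi_free:
            state["phi"] = state["phi"] + gamma * (state["phi_sample"] - state["phi"])

    # box bounds on log(A50), log(F50), log(BICAR.MV power)
    _PHI_LO = np.log([1.0, 1.0, 0.05])
    _PHI_HI = np.log([1e5, 1e5, 5.0])

    def _trace_row(self, state, k, burn):
        fx = _fx_from_state(state, self.init.fixed, self.batch.covmodel)
        row = {"iteration": k, "phase": "burn" if burn else "smooth"}
        row.update({
            "bicar0_pop": fx.bicar0_pop, "kout": fx.kout, "a50": fx.a50,
            "fur50": fx.fur50, "mv0_pop": fx.mv0_pop,
            "paco2_0_pop": fx.paco2_0_pop, "pow_bicar_mv": fx.pow_bicar_mv,
            "pow_mv_paco2": fx.pow_mv_paco2, "beta_saps": fx.beta_saps,
            "beta_chloride": fx.beta_chloride, "cortico_mult": fx.cortico_mult,
            "va_mult": fx.va_mult, "female_mult": fx.female_mult,
        })
        for j, nm in enumerate(ETA_NAMES):
            row[f"omega_{nm}"] = state["omega"][j]
        for d, nm in enumerate(("bicar", "mv", "paco2")):
            row[f"sigma_{nm}"] = state["sigma"][d]
        return row

    def _posterior_pass(self, state, sampler: _Sampler, rng):
        """Extra MCMC at the final estimates: eta means/SDs and samples."""
        config = self.config
        omega_samp = np.maximum(state["omega"], config.omega_sampling_floor)
        sampler.refresh(state)
        n_keep = config.n_post_samples
        warmup = max(10, n_keep // 5)
        samples = np.empty((n_keep, self.batch.n, 5))
        for t in range(warmup + n_keep):
            mu = sampler.transition(state, omega_samp, adapt=False)
            if t >= warmup:
                samples[t - warmup] = sampler.z - mu
        return {
            "samples": samples,
            "eta_mean": samples.mean(axis=0),
            "eta_sd": samples.std(axis=0, ddof=1),
        }

    def estimate(self):
        """Run SAEM and assemble the final parameter bundle."""
        self.phi_scale = 1.0
        zero_iterations = self.config.n_burn + self.config.n_smooth == 0
        if zero_iterations:
            state = self.initial_state()
            sampler = _Sampler(self.batch, self.config, self.eta_free,
                               np.random.default_rng(self.config.seed))
            sampler.refresh(state)
            post = self._posterior_pass(state, sampler,
                                        np.random.default_rng(self.config.seed))
            trace = pd.DataFrame()
        else:
            state, sampler, trace, post = self.run()
        if zero_iterations:
            # identity contract: the log-scale round trip must not perturb
            # the initial values
            fx = self.init.fixed
        else:
            fx = _fx_from_state(state, self.init.fixed, self.batch.covmodel)
        random = RandomEffects(**{f"omega_{nm}": float(state["omega"][j])
                                  for j, nm in enumerate(ETA_NAMES)})
        residual = ResidualError(
            sigma_bicar=float(state["sigma"][0]),
            sigma_mv=float(state["sigma"][1]),
            sigma_paco2=float(state["sigma"][2]),
        )
        params = PopulationParameters(
            fixed=fx, random=random, residual=residual,
            fixed_mask=self.init.fixed_mask)
        if not np.all(np.isfinite(state["phi"])) or not np.isfinite(
                fx.bicar0_pop * fx.kout * fx.mv0_pop):
            raise RuntimeError("SAEM diverged to non-finite estimates; see trace")
        rse = None
        if self.config.compute_rse:
            try:
                rse = compute_rse(self, state, post)
            except np.linalg.LinAlgError:  # pragma: no cover
                warnings.warn("Fisher information singular; %rse unavailable")
        return {
            "params": params, "state": state, "trace": trace,
            "eta_mean": post["eta_mean"], "eta_sd": post["eta_sd"],
            "samples": post["samples"], "rse": rse, "n_free": self.n_free,
        }


def compute_rse(saem: SAEM, state, post) -> dict:
    """%RSE from the empirical Fisher information of per-subject scores.

    Per-subject marginal scores are obtained through Fisher's identity
    (posterior expectation of the complete-data score over the stored
    MCMC draws); the information matrix is the sum of their outer
    products, which is consistent at the MLE for i.i.d. subjects.
    Scores are analytic for everything except (A50, F50, BICAR.MV
    power), which use central finite differences of the observation
    log-likelihood.
    """
    batch = saem.batch
    samples = post["samples"]
    n_samp = samples.shape[0]
    sampler = _Sampler(batch, saem.config, saem.eta_free,
                       np.random.default_rng(0))
    mu = sampler.mu(state)
    omega = np.maximum(state["omega"], 1e-6)
    sigma = state["sigma"]
    phi = state["phi"]

    names: list[str] = []
    blocks: list[tuple] = []
    covb = batch.covmodel.bicar0
    names += ["log_bicar0_pop"] + [f"bicar0:{c}" for c in covb]
    blocks.append(("reg", 0, batch.X_bicar))
    names += ["log_kout"]
    blocks.append(("reg", 1, np.ones((batch.n, 1))))
    names += ["log_mv0_pop"] + [f"mv0:{c}" for c in batch.covmodel.mv0]
    blocks.append(("reg", 2, batch.X_mv))
    names += ["log_paco2_0"]
    blocks.append(("reg", 3, np.ones((batch.n, 1))))
    names += ["log_pow_mv_paco2"]
    blocks.append(("reg", 4, np.ones((batch.n, 1))))
    for j, nm in enumerate(ETA_NAMES):
        if saem.eta_free[j]:
            names.append(f"omega_{nm}")
    for nm in ("bicar", "mv", "paco2"):
        names.append(f"sigma_{nm}")
    phi_names = np.array(["log_a50", "log_fur50", "log_pow_bicar_mv"])
    names += list(phi_names[saem.phi_free])

    scores = np.zeros((batch.n, len(names)))
    delta = 1e-4
    obs_ll_cache = {}

    def obs_ll_matrix(phi_eval):
        key = tuple(np.round(phi_eval, 12))
        if key not in obs_ll_cache:
            acc = np.zeros((n_samp, batch.n))
            for t in range(n_samp):
                psi = np.exp(mu + samples[t])
                ll, _, _ = sampler.subject_loglik(psi, phi_eval, sigma)
                acc[t] = ll
            obs_ll_cache[key] = acc
        return obs_ll_cache[key]

    col = 0
    for kind, j, X in blocks:
        eta_j = samples[:, :, j]                      # (n_samp, n)
        mean_eta = eta_j.mean(axis=0)
        score_mu = mean_eta / omega[j] ** 2           # d/d(mu_ij)
        ncol = X.shape[1]
        scores[:, col:col + ncol] = X * score_mu[:, None]
        col += ncol
    for j in range(5):
        if not saem.eta_free[j]:
            continue
        eta2 = (samples[:, :, j] ** 2).mean(axis=0)
        scores[:, col] = eta2 / omega[j] ** 3 - 1.0 / omega[j]
        col += 1
    # sigma scores: need residuals per draw
    sig_scores = np.zeros((batch.n, 3))
    for t in range(n_samp):
        psi = np.exp(mu + samples[t])
        _, b_obs, pred = sampler.subject_loglik(psi, phi, sigma)
        z2 = ((batch.obs_y - pred) / (sigma[batch.obs_dvid] * pred)) ** 2
        for d in range(3):
            mask = batch.obs_dvid == d
            per_sub = np.bincount(batch.obs_sub[mask],
                                  weights=(z2[mask] - 1.0), minlength=batch.n)
            sig_scores[:, d] += per_sub / sigma[d]
    scores[:, col:col + 3] = sig_scores / n_samp
    col += 3
    for p in saem.phi_free:
        up, down = phi.copy(), phi.copy()
        up[p] += delta
        down[p] -= delta
        grad = (obs_ll_matrix(up).mean(axis=0)
                - obs_ll_matrix(down).mean(axis=0)) / (2 * delta)
        scores[:, col] = grad
        col += 1

    info = scores.T @ scores
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    out = {}
    fx = _fx_from_state(state, saem.init.fixed, batch.covmodel)
    value_map = {
        "log_bicar0_pop": ("bicar0_pop", fx.bicar0_pop, True),
        "log_kout": ("kout", fx.kout, True),
        "log_mv0_pop": ("mv0_pop", fx.mv0_pop, True),
        "log_paco2_0": ("paco2_0_pop", fx.paco2_0_pop, True),
        "log_pow_mv_paco2": ("pow_mv_paco2", fx.pow_mv_paco2, True),
        "bicar0:saps2": ("beta_saps", fx.beta_saps, False),
        "bicar0:chloride": ("beta_chloride", fx.beta_chloride, False),
        "bicar0:corticosteroid": ("cortico_mult", fx.cortico_mult, True),
        "mv0:volume_assist": ("va_mult", fx.va_mult, True),
        "mv0:female": ("female_mult", fx.female_mult, True),
        "log_a50": ("a50", fx.a50, True),
        "log_fur50": ("fur50", fx.fur50, True),
        "log_pow_bicar_mv": ("pow_bicar_mv", fx.pow_bicar_mv, True),
    }
    for name, s in zip(names, se):
        if name in value_map:
            out_name, value, log_scale = value_map[name]
            # for log-scale parameters the SE of the log is already the
            # relative standard error
            out[out_name] = 100.0 * s if log_scale else (
                100.0 * s / abs(value) if value != 0 else np.nan)
        elif name.startswith("omega_") or name.startswith("sigma_"):
            current = {**{f"omega_{nm}": state["omega"][j]
                          for j, nm in enumerate(ETA_NAMES)},
                       **{f"sigma_{nm}": state["sigma"][d]
                          for d, nm in enumerate(("bicar", "mv", "paco2"))}}
            value = current[name]
            out[name] = 100.0 * s / value if value > 0 else np.nan
    return out
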