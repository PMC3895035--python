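# Methods

## The model

`azapd` describes three linked observables in mechanically ventilated
COPD patients treated with intravenous acetazolamide for metabolic
alkalosis.

**Drug amount.** Acetazolamide is given as brief IV boluses, so the
amount of drug in the body is a superposition of mono-exponential
decays, A(t) = Σ_{tᵢ≤t} Dᵢ·exp(−k_e(t−tᵢ)) with k_e = ln2/t½ and
t½ = 0.25 day (6 h), fixed. Amounts are right-continuous at dose
times: an observation charted at a dose time is post-dose. Furosemide
co-medication uses the same one-compartment bolus model; no
elimination constant is available for it in this context, so its
half-life defaults to the same 0.25 day and is configurable
(`FixedEffects.fur_half_life`).

**Bicarbonate turnover.** Serum bicarbonate B follows an
indirect-response model,

    dB/dt = k_in·(1 + F/(F+F₅₀)) − k_out·(1 + E_max·A/(A+A₅₀))·B,

with acetazolamide placed as a stimulation of elimination (it blocks
renal bicarbonate reabsorption, so it lowers B) and furosemide as a
stimulation of formation (it raises B). The system starts at
equilibrium, which ties the formation rate to the baseline:
k_in = k_out·Bicar₀. E_max is fixed at 1: E_max and A₅₀ are not
jointly identifiable from amount-driven data, so the curve's scale is
carried by A₅₀ alone.

**Physiological chain.** Minute ventilation responds inversely to
bicarbonate through a power law anchored at a fixed reference of
37.5 mmol/L,

    MV(t) = MV₀ · m_vent · m_sex · (37.5 / B(t))^p_BM,

where m_vent = 0.92 under volume-assist ventilation (1 under pressure
support), m_sex = 0.82 for women, and p_BM ≈ 0.67. PaCO2 responds
inversely to minute ventilation relative to the subject's own model
baseline MV(0),

    PaCO2(t) = PaCO2₀ · (MV(0) / MV(t))^p_MP,   p_MP ≈ 0.71.

Because MV(0) includes the same ventilator-mode and sex multipliers as
MV(t), they cancel in the ratio: PaCO2 depends on the mode only
through the bicarbonate path, and PaCO2(0) = PaCO2₀ identically. Where
the placement of a multiplier was ambiguous (the ventilator-mode
effect could act on MV₀ or on the PaCO2 equilibrium), the package
follows the parameter table of the source analysis and places it on
MV₀.

**Hierarchy.** Individual parameters are log-normal,
ψᵢ = ψ_pop,cov·exp(ηᵢ), ηᵢ ~ N(0, ω²) independent per parameter
(Bicar₀, k_out, MV₀, PaCO2₀ and the MV→PaCO2 power carry
between-subject variability; A₅₀, F₅₀, the B→MV power and the fixed
constants do not). Covariates act multiplicatively: Bicar₀ is scaled
by (SAPS II/50)^β_S, (chloride/100)^β_Cl and a corticosteroid
multiplier; MV₀ by the ventilator-mode and sex multipliers. On the log
scale every one of these relationships is exactly linear, which the
estimator exploits. Residual error is proportional per observation
type, y = f·(1+ε), ε ~ N(0, σ²) — a constant coefficient of variation.

Default parameter values (`default_population()`) are the published
population estimates for the 68-patient cohort; they are the
generating truth for every simulation and recovery experiment in the
package.

## Integrating the turnover equation

The turnover ODE is linear and scalar with piecewise-exponential
coefficients, so between dose times it has the exact
integrating-factor representation

    B(t₀+τ) = B(t₀)·e^{−β(τ)} + ∫₀^τ a(s)·e^{β(s)−β(τ)} ds,

where β(τ) = ∫₀^τ k_out(1+E_max·A/(A+A₅₀)) has a closed form (the
drug integral is a logarithm) and the remaining integral is evaluated
with 16-point Gauss–Legendre quadrature. Segments are capped at
0.25 day, which keeps the quadrature at machine precision for any
plausible k_out; in the stiff limit (β(τ) > 15, reached only by
extreme random-effect draws in likelihood tails) the solution is
replaced by its quasi-static limit a(τ)/b(τ), exact to O(k_e/b). This
integrator is vectorised over thousands of (subject, replicate) rows
and is exact at dose discontinuities.

An adaptive Runge–Kutta path (scipy `solve_ivp`, rtol 1e-8/atol 1e-10,
dose times forced as breakpoints) handles arbitrary drug inputs —
notably clamped constant amounts for steady-state analyses — and
serves as the independent cross-check of the exact path in the test
suite. Unsorted dose lists are rejected rather than silently sorted.

## SAEM estimation

`AcetazolamidePD.fit` maximises the exact (non-linearised) likelihood
by stochastic-approximation EM:

* **E-step.** A Metropolis random walk per subject, vectorised across
  the cohort, with two blocks: (Bicar₀ᵢ, k_outᵢ), which require an ODE
  pass, and (MV₀ᵢ, PaCO2₀ᵢ, p_MPᵢ), which are algebraic given the
  cached bicarbonate trajectory. The chain state is the individual
  log-parameter matrix itself rather than the deviation η: individuals
  then stay anchored to their data when the M-step moves population
  coefficients, which removes a feedback random walk that would
  otherwise afflict weakly informed covariate coefficients. Proposal
  scales adapt per subject toward 30–40% acceptance during burn-in.
* **Stochastic approximation.** Sufficient statistics are averaged
  over the within-iteration MCMC sweeps (same fixed point, lower
  noise) and smoothed with gain 1 during burn-in and k^(−0.7)
  afterwards.
* **M-step.** Closed form throughout the log-linear part: each
  population block is an ordinary least-squares regression of the
  smoothed log-individual values on its covariate design matrix
  (intercept = log population median; slopes = covariate exponents or
  log multipliers), ω² from the residual second moments, σ² from the
  accumulated squared proportional residuals.
* **Structural parameters without variability** (A₅₀, F₅₀, p_BM) run
  in their own Metropolis chain against the full-cohort observation
  likelihood, with an artificial Gaussian prior centred at the current
  population value whose SD anneals from 0.15 (log scale) to a 0.05
  floor; the population value tracks the chain by the same stochastic
  approximation. This is the standard annealed artificial-variability
  device: the chain can traverse the (k_out, A₅₀) likelihood ridge
  early and is pinned down as the gain decreases. F₅₀ is only
  estimated when the dataset contains furosemide doses. Box bounds
  (amounts in [1, 10⁵] mg, power in [0.05, 5]) keep proposals
  physiological.

Defaults: 150 burn-in and 300 smoothing iterations, 4 MCMC sweeps per
iteration, with the structural chain run at triple rate during
burn-in. During burn-in the sampling SD of every random effect is
floored at 0.05 so exploration survives an early collapse of an ω
estimate; the floor drops to 0.005 in the smoothing phase. These
choices were selected for convergence quality on study-design
cohorts — on a near-noiseless rich design the estimator recovers all
structural parameters within ~1–2%, and on 68-subject study-design
cohorts the population baselines within a few percent with k_out and
A₅₀ inside their sampling uncertainty (both are weakly identified at
n = 68: k_out carries ~100% between-subject variability, and only two
dose levels inform A₅₀).

**Uncertainty.** Relative standard errors come from the empirical
Fisher information of per-subject marginal scores, obtained through
Fisher's identity as posterior expectations of the complete-data score
over 100 post-run MCMC draws; the score is analytic for every
parameter except (A₅₀, F₅₀, p_BM), which use central finite
differences of the observation log-likelihood.

**Marginal likelihood.** Importance sampling with a t(4) proposal
centred at each subject's posterior η mean. Proposal SDs are the
posterior SDs inflated by 2 (short correlated chains underestimate
posterior width; a too-narrow proposal biases the estimate low) with a
floor of ω/4. AIC = −2·LL + 2k with k the number of free parameters;
the likelihood-ratio test applies to nested covariate models, and
forward selection adds the candidate with the best AIC improvement
until none improves.

## Diagnostics

NPDE are computed against full-model Monte-Carlo replicates of each
subject's observation vector (default 500, as in the source analysis).
Observed and simulated vectors are decorrelated with the Cholesky
factor of the empirical simulated covariance; the decorrelated
observation is deflated by the first-order finite-simulation factor
√((1+1/n)(n−1)/(n−L−2)) — whitening with a covariance estimated from
the simulations alone would otherwise inflate its variance relative to
the whitened cloud. Rank ties are broken with the
(rank + U(0,1))/(n_sim+1) jitter, quantiles are clipped away from 0
and 1, and npde = Φ⁻¹(pd). Calibration is checked with a Wilcoxon
signed-rank test of zero mean, a two-sided chi-square test of unit
variance (the "variance test"), and Shapiro–Wilk normality. A singular
simulated covariance is ridge-regularised with a warning. Because the
decorrelation matrix is estimated, ~L/n_sim of residual within-subject
correlation leaks into the variance test; calibration experiments in
the test suite therefore use 1000–2000 simulations, while 500 remains
the default for routine diagnostics.

Shrinkage is 1 − sd(η)/ω per random effect; observed-vs-predicted
tables report population (η = 0) and individual (posterior-mean η)
predictions with through-origin identity slopes.

## The synthetic cohort

`generate_cohort` emulates the study design: 68 subjects, 250 or
500 mg IV acetazolamide twice daily over a 4-day weaning window,
~9 minute-ventilation observations per subject (range 2–14, uniform
over the window) and ~3 paired blood-gas observations (range 1–6) —
cohort totals near 619 and 207. Covariate distributions are not
published, so the defaults are explicit assumptions centring the
covariate normalisers: SAPS II log-normal (median 50, CV 30%),
chloride normal (100 ± 5 mmol/L, truncated positive), corticosteroids
30%, female 30%, volume-assist 50%, furosemide co-medication 30% at
40 mg/day. Every subject draws from a deterministic sub-seed of the
master seed, so a cohort is byte-identical across runs.

What the generator does *not* emulate: real covariate correlations,
dropout, dose titration by the treating physician, respiratory
rate/tidal volume decomposition, or model misspecification of any
kind. Passing recovery and calibration tests therefore demonstrates
internal consistency of estimator and diagnostics under the model, not
correctness of the model for real patients.

## Dose-regimen simulation

`simulate_regimen` draws virtual subjects (covariates + random
effects) from the cohort distributions, integrates the chain under a
regimen, and reports per-subject changes from the pre-dose model value
to the evaluation horizon. The default horizon is 1 day — the change
from baseline to 24 h after the first once-daily administration, the
same contrast charted for the observed data. With k_out ≈ 0.314/day a
multi-day horizon would sit near the treatment steady state and push
nearly every subject past the responder thresholds, so the 24-h
contrast is the one under which the published responder proportions
(about 65%/60% of patients gaining > 0.75 L/min of minute ventilation
under pressure-support/volume-assist ventilation, and about 45%
dropping PaCO2 by > 5 mmHg at 1000 mg/day) are reproducible; longer
horizons remain available through `RegimenSpec`.

By default the endpoints carry proportional measurement noise: the
deltas are differences of *observable* charted values, the scale on
which the clinical thresholds are defined and on which the observed
pre/post contrasts were reported. Whether the original simulations
included residual error is not documented; the observable-delta
convention is the one under which all the published responder
proportions are reproduced simultaneously (latent-chain deltas
understate the PaCO2 responders, because the median latent drop at
24 h is below 5 mmHg while the measured drop clears it in nearly half
of patients). The latent chain is available with
`include_residual=False`. Responder thresholds are strict
inequalities. The same seed reuses the same virtual subjects — and
the same noise draws — across doses, so dose-response contrasts are
paired and median monotonicity in dose is exact.

## Known limitations

* The placement of the drug effects (stimulation of elimination for
  acetazolamide, of formation for furosemide) is mechanistically
  motivated but not uniquely determined by the available summary of
  the original analysis.
* A₅₀ and k_out lie on a likelihood ridge at the study design (two
  dose levels, amount-driven kinetics); their joint recovery at n = 68
  is correspondingly loose, which the acceptance tolerances reflect.
* The between-subject variability of the MV→PaCO2 power is estimated
  on the log scale like every other random effect; the original
  convention for that parameter is not documented.
* Whether 37.5 mmol/L is a cohort median or a fitted constant is
  unknown; it is treated as a fixed structural reference.
* Covariance between random effects is assumed zero (diagonal Ω).
* Furosemide kinetics are an assumption (no half-life is available);
  its effect is small at 40 mg/day and F₅₀ ≈ 204 mg.
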