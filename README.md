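# azapd — population pharmacodynamics of acetazolamide in ventilated COPD patients

COPD patients weaned from invasive mechanical ventilation often develop
metabolic alkalosis: elevated serum bicarbonate blunts the respiratory
drive, keeping minute ventilation low and arterial CO2 high.
Acetazolamide, a carbonic-anhydrase inhibitor, lowers serum bicarbonate
and can restore the drive — but the usual 250–500 mg doses have a
modest effect, and the dose that *would* help can only be explored by
simulation from a population model.

`azapd` implements that model as a nonlinear mixed-effects package for
pharmacometricians and intensive-care researchers:

* **Structural model.** The amount of drug in the body after IV
  boluses is A(t) = Σ Dᵢ·exp(−(ln2/t½)(t−tᵢ)) with t½ = 6 h.
  Serum bicarbonate follows an indirect-response (turnover) equation
  in which acetazolamide stimulates elimination and co-medicated
  furosemide stimulates formation,

      dB/dt = k_in·(1 + F/(F+F₅₀)) − k_out·(1 + E_max·A/(A+A₅₀))·B,
      k_in = k_out·Bicar₀  (equilibrium start),

  and two power laws chain bicarbonate to minute ventilation and
  PaCO2: MV = MV₀·(37.5/B)^0.67 (times 0.92 under volume-assist
  ventilation and 0.82 for women) and PaCO2 = PaCO2₀·(MV₀/MV)^0.71.
* **Hierarchy.** Individual parameters are log-normal around
  covariate-adjusted population values (SAPS II, serum chloride and
  corticosteroid use act on Bicar₀); residual error is proportional.
* **Estimation.** SAEM (stochastic-approximation EM) with per-subject
  MCMC — no linearisation — plus importance-sampling marginal
  likelihood, AIC/LRT model comparison and forward covariate selection.
* **Diagnostics.** NPDE with full decorrelation, Wilcoxon/variance
  calibration tests, eta-shrinkage, observed-vs-predicted tables.
* **Simulation.** A synthetic-cohort generator emulating the original
  68-patient study design, and a Monte-Carlo dose-regimen simulator
  for the high-dose predictions.

## Worked example

```python
import azapd

# 1. a synthetic cohort with the published estimates as truth
truth = azapd.default_population()
cohort = azapd.generate_cohort(truth, azapd.study_design(seed=1))
print(azapd.summarize_cohort(cohort)[["n_obs", "median_per_subject"]])

# 2. refit it by SAEM
model = azapd.AcetazolamidePD(cohort, init=truth)
res = model.fit(azapd.SaemConfig(seed=4))
print(f"Bicar0 {res.params.fixed.bicar0_pop:.1f} mmol/L, "
      f"kout {res.params.fixed.kout:.3f}/day, A50 {res.params.fixed.a50:.0f} mg")

# 3. what would 1000 mg once daily do?
deltas = azapd.simulate_regimen(truth, azapd.RegimenSpec(daily_dose=1000),
                                n_subjects=10_000, seed=17, mode="psv")
props = azapd.responder_proportions(deltas)["all"]
print(f"MV rise > 0.75 L/min in {100*props['p_mv']:.0f}% of patients, "
      f"PaCO2 drop > 5 mmHg in {100*props['p_paco2']:.0f}%")
```

This prints (cohort summary abridged):

```
       n_obs  median_per_subject
dvid
BICAR    202                 3.0
MV       607                 9.0
PACO2    202                 3.0
Bicar0 35.4 mmol/L, kout 0.342/day, A50 194 mg
MV rise > 0.75 L/min in 57% of patients, PaCO2 drop > 5 mmHg in 49%
```

— the generator reproduces the study's observation design (~619
minute-ventilation and ~207 blood-gas records over 68 subjects), the
fit recovers the generating parameters within their sampling
uncertainty, and at 1000 mg/day a majority of virtual patients gain a
clinically relevant increase in minute ventilation 24 h after dosing,
with nearly half dropping PaCO2 by more than 5 mmHg.

A command-line interface wraps the same pipeline:

```bash
azapd simulate-cohort --seed 1 --out cohort/
azapd fit --data cohort/dataset.csv --seed 4 --out fit/
azapd diagnose --data cohort/dataset.csv --params fit/params.json --out diag/
azapd simulate-dose --regimens 250,500,1000,2000 --out dose/
```

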