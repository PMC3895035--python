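"""Synthetic-cohort generator emulating the ventilated-COPD study design.

The emulated design: 68 subjects receiving 250-500 mg IV acetazolamide
twice daily over a multi-day weaning window, with ~9 minute-ventilation
observations per subject (range 2-14) and ~3 paired blood-gas
(bicarbonate + PaCO2) observations per subject (range 1-6), for cohort
totals near 619 MV and 207 bicarbonate/PaCO2 observations.

Covariate distributions are not published for the real cohort; the
defaults centre the covariate normalisers (SAPS II 50, chloride
100 mmol/L) and use plausible ICU prevalences for the binary flags.
They are explicit assumptions, overridable through
:class:`DesignConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import population, turnover
from .dataset import Dataset, Dvid, Observation, SubjectRecord
from .kinetics import DoseEvent, Drug
from .params import Covariates, PopulationParameters


@dataclass(frozen=True)
class CountSpec:
    """Per-subject observation count: rounded truncated normal."""

    mean: float
    sd: float
    minimum: int
    maximum: int

    def draw(self, rng) -> int:
        k = int(round(rng.normal(self.mean, self.sd)))
        return int(np.clip(k, self.minimum, self.maximum))


@dataclass(frozen=True)
class DesignConfig:
    n_subjects: int = 68
    dose_choices: tuple = (250.0, 500.0)   # mg per administration
    dose_interval: float = 0.5             # day (twice daily)
    duration: float = 4.0                  # treatment window, day
    mv_counts: CountSpec = field(default_factory=lambda: CountSpec(9.1, 3.0, 2, 14))
    bg_counts: CountSpec = field(default_factory=lambda: CountSpec(3.0, 1.2, 1, 6))
    saps2_median: float = 50.0
    saps2_cv: float = 0.30
    chloride_mean: float = 100.0
    chloride_sd: float = 5.0
    p_corticosteroid: float = 0.3
    p_female: float = 0.3
    p_volume_assist: float = 0.5
    p_furosemide: float = 0.3
    furosemide_dose: float = 40.0          # mg once daily
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration <= 0 or self.dose_interval <= 0:
            raise ValueError("duration and dose_interval must be positive")


def draw_covariates(design: DesignConfig, rng) -> Covariates:
    sdlog = np.sqrt(np.log1p(design.saps2_cv ** 2))
    saps2 = float(np.exp(np.log(design.saps2_median) + sdlog * rng.standard_normal()))
    chloride = 0.0
    while chloride <= 0:
        chloride = float(rng.normal(design.chloride_mean, design.chloride_sd))
    return Covariates(
        saps2=saps2,
        chloride=chloride,
        corticosteroid=bool(rng.random() < design.p_corticosteroid),
        female=bool(rng.random() < design.p_female),
        volume_assist=bool(rng.random() < design.p_volume_assist),
    )


def _dose_list(design: DesignConfig, rng):
    amount = float(rng.choice(np.asarray(design.dose_choices)))
    times = np.arange(0.0, design.duration - 1e-9, design.dose_interval)
    doses = [DoseEvent(float(t), amount, Drug.ACETAZOLAMIDE) for t in times]
    if rng.random() < design.p_furosemide and design.furosemide_dose > 0:
        fur_times = np.arange(0.0, design.duration - 1e-9, 1.0)
        doses += [DoseEvent(float(t), design.furosemide_dose, Drug.FUROSEMIDE)
                  for t in fur_times]
    return doses


def generate_subject(truth: PopulationParameters, design: DesignConfig,
                     subject_id: int, rng) -> SubjectRecord:
    cov = draw_covariates(design, rng)
    ind = population.sample_individual(truth.fixed, truth.random, cov, rng)
    doses = _dose_list(design, rng)
    n_mv = design.mv_counts.draw(rng)
    n_bg = design.bg_counts.draw(rng)
    t_mv = np.sort(rng.uniform(0.0, design.duration, n_mv))
    t_bg = np.sort(rng.uniform(0.0, design.duration, n_bg))
    ace = [d for d in doses if d.drug is Drug.ACETAZOLAMIDE]
    fur = [d for d in doses if d.drug is Drug.FUROSEMIDE]
    record = SubjectRecord(id=subject_id, covariates=cov, doses=list(doses))
    fx, res = truth.fixed, truth.residual

    def bicar_at(times):
        if times.size == 0:
            return times
        return turnover.bicar_trajectory(ind, fx, ace, fur, times)

    b_mv, b_bg = bicar_at(t_mv), bicar_at(t_bg)
    mv_base = turnover.mv_baseline(ind, fx, cov)
    for t, b in zip(t_mv, b_mv):
        pred = turnover.mv_from_bicar(ind, fx, cov, b)
        record.observations.append(
            Observation(float(t), Dvid.MV, float(population.observe(pred, res.sigma_mv, rng))))
    for t, b in zip(t_bg, b_bg):
        pred_b = float(b)
        mv = turnover.mv_from_bicar(ind, fx, cov, b)
        pred_p = turnover.paco2_from_mv(ind, mv, mv_base)
        record.observations.append(
            Observation(float(t), Dvid.BICAR,
                        float(population.observe(pred_b, res.sigma_bicar, rng))))
        record.observations.append(
            Observation(float(t), Dvid.PACO2,
                        float(population.observe(pred_p, res.sigma_paco2, rng))))
    record.observations.sort(key=lambda o: (o.time, o.dvid.value))
    return record


def generate_cohort(truth: PopulationParameters, design: DesignConfig) -> Dataset:
    """Generate a full cohort, reproducible from ``design.seed``.

    Per-subject RNG streams are spawned deterministically from the
    master seed, so the dataset is byte-identical across runs and
    insensitive to generation order.
    """
    seeds = np.random.SeedSequence(design.seed).spawn(design.n_subjects)
    subjects = [
        generate_subject(truth, design, i + 1, np.random.default_rng(seeds[i]))
        for i in range(design.n_subjects)
    ]
    return Dataset(subjects=subjects)


def summarize_cohort(dataset: Dataset) -> pd.DataFrame:
    """Per-observation-type totals, value summaries and per-subject counts."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rows = []
    for dvid in Dvid:
        values = np.array([o.value for s in dataset for o in s.observations
                           if o.dvid is dvid])
        counts = np.array([s.n_obs(dvid) for s in dataset])
        rows.append({
            "dvid": dvid.value,
            "n_obs": int(values.size),
            "mean": float(values.mean()) if values.size else np.nan,
            "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
            "median_per_subject": float(np.median(counts)),
            "min_per_subject": int(counts.min()),
            "max_per_subject": int(counts.max()),
        })
    return pd.DataFrame(rows).set_index("dvid")


def study_design(seed: int = 0, **overrides) -> DesignConfig:
    """The default study-design emulation with a chosen master seed."""
    return replace(DesignConfig(seed=seed), **overrides)
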