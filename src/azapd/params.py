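"""Parameter containers for the acetazolamide pharmacodynamic model.

The model couples three observable processes in mechanically ventilated
COPD patients treated with intravenous acetazolamide for metabolic
alkalosis:

* serum bicarbonate ``Bicar(t)`` follows an indirect-response (turnover)
  model in which acetazolamide stimulates bicarbonate elimination and
  furosemide stimulates bicarbonate formation;
* minute ventilation ``MV(t)`` is linked to bicarbonate through a power
  law ``(bicar_ref / Bicar(t)) ** pow_bicar_mv`` (alkalosis blunts
  respiratory drive, so MV rises as bicarbonate falls);
* arterial CO2 tension ``PaCO2(t)`` is linked to minute ventilation
  through ``(MV_baseline / MV(t)) ** pow_mv_paco2``.

Default values are the published population estimates from the
68-patient ventilated-COPD cohort this package models; they serve as
the generating truth for simulation and recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class FixedEffects:
    """Population-level structural and covariate parameters.

    Units: baselines in mmol/L (bicarbonate), L/min (minute
    ventilation), mmHg (PaCO2); rate constants in 1/day; drug amounts
    in mg; half-lives in days; covariate exponents and multipliers
    dimensionless.
    """

    bicar0_pop: float = 35.4      # bicarbonate baseline, mmol/L
    kout: float = 0.314           # bicarbonate turnover rate, /day
    a50: float = 163.0            # acetazolamide amount for half-maximal effect, mg
    emax: float = 1.0             # maximal fractional stimulation of kout (fixed)
    fur50: float = 204.0          # furosemide amount for half-maximal effect, mg
    mv0_pop: float = 11.1         # baseline minute ventilation, L/min
    paco2_0_pop: float = 54.4     # baseline PaCO2, mmHg
    half_life: float = 0.25       # acetazolamide elimination half-life, day (6 h, fixed)
    fur_half_life: float = 0.25   # furosemide elimination half-life, day (assumed, fixed)
    beta_saps: float = -0.11      # exponent on (SAPS II / 50) for Bicar0
    beta_chloride: float = -1.17  # exponent on (chloride / 100) for Bicar0
    cortico_mult: float = 1.10    # Bicar0 multiplier if corticosteroids present
    va_mult: float = 0.92         # MV0 multiplier under volume-assist ventilation
    female_mult: float = 0.82     # MV0 multiplier if female
    pow_bicar_mv: float = 0.67    # exponent on (bicar_ref / Bicar) in the MV link
    bicar_ref: float = 37.5       # reference bicarbonate in the MV link, mmol/L (fixed)
    pow_mv_paco2: float = 0.71    # exponent on (MV_baseline / MV) in the PaCO2 link

    def __post_init__(self):
        _require_positive(
            self,
            [
                "bicar0_pop", "kout", "a50", "fur50", "mv0_pop",
                "paco2_0_pop", "half_life", "fur_half_life",
                "cortico_mult", "va_mult", "female_mult", "bicar_ref",
            ],
        )
        if not 0 < self.emax <= 1:
            raise ValueError(f"emax must lie in (0, 1], got {self.emax!r}")


@dataclass(frozen=True)
class RandomEffects:
    """Between-subject variability: SDs of log-normal random effects."""

    omega_bicar0: float = 0.10
    omega_kout: float = 0.995
    omega_mv0: float = 0.225
    omega_paco2_0: float = 0.102
    omega_pow_mv_paco2: float = 0.56

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def as_array(self):
        import numpy as np

        return np.array(
            [
                self.omega_bicar0,
                self.omega_kout,
                self.omega_mv0,
                self.omega_paco2_0,
                self.omega_pow_mv_paco2,
            ]
        )


@dataclass(frozen=True)
class ResidualError:
    """Proportional residual-error SDs per observation type.

    Zero is accepted for noise-free simulation; estimation requires
    strictly positive values.
    """

    sigma_bicar: float = 0.044
    sigma_mv: float = 0.16
    sigma_paco2: float = 0.12

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


DEFAULT_FIXED_MASK = ("emax", "half_life", "fur_half_life", "bicar_ref")


@dataclass(frozen=True)
class PopulationParameters:
    """Bundle of fixed effects, between-subject variability and residual error."""

    fixed: FixedEffects = field(default_factory=FixedEffects)
    random: RandomEffects = field(default_factory=RandomEffects)
    residual: ResidualError = field(default_factory=ResidualError)
    fixed_mask: tuple = DEFAULT_FIXED_MASK

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {f.name: getattr(self.fixed, f.name) for f in fields(FixedEffects)},
            "random_effects": {f.name: getattr(self.random, f.name) for f in fields(RandomEffects)},
            "residual": {f.name: getattr(self.residual, f.name) for f in fields(ResidualError)},
            "fixed_mask": list(self.fixed_mask),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationParameters":
        expected = {"fixed_effects", "random_effects", "residual", "fixed_mask"}
        unknown = set(data) - expected
        if unknown:
            raise ValueError(f"unknown parameter-file blocks: {sorted(unknown)}")
        blocks = {}
        for block, klass in [
            ("fixed_effects", FixedEffects),
            ("random_effects", RandomEffects),
            ("residual", ResidualError),
        ]:
            payload = data.get(block, {})
            known = {f.name for f in fields(klass)}
            bad = set(payload) - known
            if bad:
                raise ValueError(f"unknown keys in {block}: {sorted(bad)}")
            blocks[block] = klass(**payload)
        mask = tuple(data.get("fixed_mask", DEFAULT_FIXED_MASK))
        known_fixed = {f.name for f in fields(FixedEffects)}
        bad = set(mask) - known_fixed
        if bad:
            raise ValueError(f"fixed_mask names unknown parameters: {sorted(bad)}")
        return cls(
            fixed=blocks["fixed_effects"],
            random=blocks["random_effects"],
            residual=blocks["residual"],
            fixed_mask=mask,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PopulationParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace_fixed(self, **kwargs) -> "PopulationParameters":
        return replace(self, fixed=replace(self.fixed, **kwargs))


def default_population() -> PopulationParameters:
    """Published population estimates for the ventilated-COPD cohort."""
    return PopulationParameters()


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates retained in the final covariate model."""

    saps2: float = 50.0        # severity score at ICU admission
    chloride: float = 100.0    # serum chloride, mmol/L
    corticosteroid: bool = False
    female: bool = False
    volume_assist: bool = False  # False = pressure-support ventilation

    def __post_init__(self):
        _require_positive(self, ["saps2", "chloride"])


@dataclass(frozen=True)
class IndividualParameters:
    """A subject's realised parameters after covariates and random effects.

    ``bicar0_i`` is fully covariate-adjusted; ``mv0_i`` excludes the
    sex/ventilator-mode multipliers, which are applied in the MV link.
    """

    bicar0_i: float
    kout_i: float
    mv0_i: float
    paco2_0_i: float
    pow_mv_paco2_i: float

    def __post_init__(self):
        _require_positive(self, ["bicar0_i", "kout_i", "mv0_i", "paco2_0_i"])
        if self.pow_mv_paco2_i < 0:
            raise ValueError("pow_mv_paco2_i must be non-negative")
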