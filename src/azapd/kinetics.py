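"""One-compartment IV-bolus drug-amount kinetics.

Acetazolamide is given as brief intravenous boluses, so the amount of
drug in the body is a superposition of mono-exponential decays:

    A(t) = sum_{t_i <= t} D_i * exp(-(ln 2 / t_half) * (t - t_i))

The amount is right-continuous at dose times (a dose is included at its
own time), matching the convention that an observation charted at a
dose time is post-dose. Furosemide co-medication uses the same model
with its own (configurable) half-life.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

LN2 = float(np.log(2.0))


class Drug(enum.Enum):
    ACETAZOLAMIDE = "ACZ"
    FUROSEMIDE = "FUR"


@dataclass(frozen=True)
class DoseEvent:
    """A single instantaneous IV bolus."""

    time: float   # day
    amount: float  # mg
    drug: Drug = Drug.ACETAZOLAMIDE

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be non-negative, got {self.amount}")


def _dose_arrays(doses):
    times = np.array([d.time for d in doses], dtype=float)
    amounts = np.array([d.amount for d in doses], dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("dose events must be sorted by time")
    return times, amounts


def drug_amount(doses, half_life: float, t) -> np.ndarray | float:
    """Amount of drug in the body at time(s) ``t`` (mg).

    Parameters
    ----------
    doses
        Time-sorted :class:`DoseEvent` list for a single drug.
    half_life
        Elimination half-life in days.
    t
        Scalar or array of times (days, non-negative).
    """
    if half_life <= 0:
        raise ValueError("half_life must be strictly positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    times, amounts = _dose_arrays(doses)
    ke = LN2 / half_life
    dt = t_arr[..., None] - times
    contrib = np.where(dt >= 0, amounts * np.exp(-ke * np.where(dt >= 0, dt, 0.0)), 0.0)
    out = contrib.sum(axis=-1) if times.size else np.zeros_like(t_arr)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def dose_times(doses) -> np.ndarray:
    return np.unique([d.time for d in doses])


def amounts_at_boundaries(doses, half_life: float, boundaries: np.ndarray) -> np.ndarray:
    """Post-dose amount at each segment boundary.

    ``boundaries`` must include every dose time of ``doses``; between
    consecutive boundaries the amount is then the pure exponential
    ``A(t) = A(t_s) * exp(-ke (t - t_s))``.
    """
    missing = set(np.round(dose_times(doses), 12)) - set(np.round(boundaries, 12))
    if missing:
        raise ValueError(f"boundaries are missing dose times: {sorted(missing)}")
    return np.asarray(drug_amount(doses, half_life, np.asarray(boundaries, dtype=float)))
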