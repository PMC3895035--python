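"""Longitudinal dataset container and the NONMEM-style CSV format.

One CSV row is either a dose event (EVID = 1: AMT, DRUG set) or an
observation (EVID = 0: DVID, DV set); covariates repeat on every row
and must be constant within a subject. Times are in days by default;
``time_unit='hour'`` converts on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .kinetics import DoseEvent, Drug
from .params import Covariates

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DRUG", "DVID", "DV",
           "SAPS2", "CHLORIDE", "CORT", "SEX", "VENT"]


class Dvid(enum.Enum):
    BICAR = "BICAR"
    MV = "MV"
    PACO2 = "PACO2"


@dataclass(frozen=True)
class Observation:
    time: float
    dvid: Dvid
    value: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("observation time must be non-negative")
        if not self.value > 0:
            raise ValueError("observed value must be strictly positive")


@dataclass
class SubjectRecord:
    """One subject: covariates, dose events for both drugs, observations."""

    id: int
    covariates: Covariates
    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)

    def doses_for(self, drug: Drug):
        return [d for d in self.doses if d.drug is drug]

    def n_obs(self, dvid: Dvid | None = None) -> int:
        if dvid is None:
            return len(self.observations)
        return sum(1 for o in self.observations if o.dvid is dvid)


@dataclass
class Dataset:
    subjects: list

    def __len__(self):
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def n_obs(self, dvid: Dvid | None = None) -> int:
        return sum(s.n_obs(dvid) for s in self.subjects)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            cov = s.covariates
            base = {
                "ID": s.id, "SAPS2": cov.saps2, "CHLORIDE": cov.chloride,
                "CORT": int(cov.corticosteroid), "SEX": int(cov.female),
                "VENT": int(cov.volume_assist),
            }
            for d in s.doses:
                rows.append({**base, "TIME": d.time, "EVID": 1, "AMT": d.amount,
                             "DRUG": d.drug.value, "DVID": "", "DV": ""})
            for o in s.observations:
                rows.append({**base, "TIME": o.time, "EVID": 0, "AMT": "",
                             "DRUG": "", "DVID": o.dvid.value, "DV": o.value})
        frame = pd.DataFrame(rows, columns=COLUMNS)
        if len(frame):
            frame = frame.sort_values(["ID", "TIME", "EVID"],
                                      ascending=[True, True, False],
                                      kind="stable").reset_index(drop=True)
        return frame


def write_dataset(dataset: Dataset, path) -> None:
    """Write the CSV with deterministic column and row order."""
    dataset.to_frame().to_csv(path, index=False)


def _fail(errors, row, message):
    errors.append(f"row {row}: {message}")


def from_frame(frame: pd.DataFrame) -> Dataset:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    errors: list[str] = []
    subjects = []
    for sid, grp in frame.groupby("ID", sort=True):
        cov_cols = grp[["SAPS2", "CHLORIDE", "CORT", "SEX", "VENT"]]
        if (cov_cols.nunique() > 1).any():
            varying = list(cov_cols.columns[(cov_cols.nunique() > 1)])
            errors.append(f"subject {sid}: covariates vary within subject: {varying}")
            continue
        first = cov_cols.iloc[0]
        try:
            cov = Covariates(
                saps2=float(first["SAPS2"]), chloride=float(first["CHLORIDE"]),
                corticosteroid=bool(int(first["CORT"])),
                female=bool(int(first["SEX"])),
                volume_assist=bool(int(first["VENT"])),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"subject {sid}: invalid covariates ({exc})")
            continue
        record = SubjectRecord(id=int(sid), covariates=cov)
        for idx, row in grp.iterrows():
            rownum = idx + 2  # header is line 1
            time = row["TIME"]
            try:
                time = float(time)
            except (TypeError, ValueError):
                _fail(errors, rownum, f"non-numeric TIME {time!r}")
                continue
            if time < 0:
                _fail(errors, rownum, f"negative TIME {time}")
                continue
            evid = row["EVID"]
            dv, amt = row["DV"], row["AMT"]
            has_dv = not (pd.isna(dv) or str(dv).strip() == "")
            has_amt = not (pd.isna(amt) or str(amt).strip() == "")
            if evid == 1:
                if has_dv:
                    _fail(errors, rownum, "DV set on a dose row")
                    continue
                if not has_amt:
                    _fail(errors, rownum, "dose row without AMT")
                    continue
                drug = str(row["DRUG"]).strip()
                if drug not in ("ACZ", "FUR"):
                    _fail(errors, rownum, f"unknown DRUG {drug!r}")
                    continue
                record.doses.append(DoseEvent(time, float(amt), Drug(drug)))
            elif evid == 0:
                if has_amt:
                    _fail(errors, rownum, "AMT set on an observation row")
                    continue
                dvid = str(row["DVID"]).strip()
                if dvid not in Dvid.__members__:
                    _fail(errors, rownum, f"unknown DVID {dvid!r}")
                    continue
                if not has_dv:
                    _fail(errors, rownum, "observation row without DV")
                    continue
                try:
                    record.observations.append(Observation(time, Dvid[dvid], float(dv)))
                except ValueError as exc:
                    _fail(errors, rownum, str(exc))
                    continue
            else:
                _fail(errors, rownum, f"EVID must be 0 or 1, got {evid!r}")
                continue
        record.doses.sort(key=lambda d: d.time)
        record.observations.sort(key=lambda o: (o.time, o.dvid.value))
        subjects.append(record)
    if errors:
        raise ValueError("dataset validation failed:\n" + "\n".join(errors))
    return Dataset(subjects=subjects)


def read_dataset(path, time_unit: str = "day") -> Dataset:
    if time_unit not in ("day", "hour"):
        raise ValueError("time_unit must be 'day' or 'hour'")
    frame = pd.read_csv(path, float_precision="round_trip")
    if time_unit == "hour":
        frame["TIME"] = pd.to_numeric(frame["TIME"]) / 24.0
    return from_frame(frame)
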