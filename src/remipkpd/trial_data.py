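"""Event-record datasets, dosing regimens and subject covariates.

The dataset layout follows the NONMEM-community convention: one long table
with dose rows (``AMT`` > 0, ``MDV`` = 1) interleaved with observation rows,
an observation-type code ``DVID`` (1 = plasma concentration, 2 = BIS,
3 = MOAA/S) and per-subject covariate columns repeated on every row.

Units are fixed package-wide: time in minutes, dose amounts in mg,
concentrations in ng mL^-1 (equivalently ug L^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LLOQ",
    "DVID_CONC",
    "DVID_BIS",
    "DVID_MOAAS",
    "SubjectCovariates",
    "DoseEvent",
    "Regimen",
    "RegimenSpec",
    "ObservationRecord",
    "ObservationTable",
    "read_dataset",
    "write_dataset",
    "resolve_regimen",
]

#: Lower limit of quantification of the plasma assay, ng mL^-1.
LLOQ = 0.5

DVID_CONC = 1
DVID_BIS = 2
DVID_MOAAS = 3

_DVID_NAMES = {DVID_CONC: "CONC", DVID_BIS: "BIS", DVID_MOAAS: "MOAAS"}


class SchemaError(ValueError):
    """Raised when a dataset file does not conform to the expected schema."""


class ValidationError(ValueError):
    """Raised when values violate domain invariants."""


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographics of one subject.

    Parameters
    ----------
    subject_id : opaque identifier (kept as given).
    weight : body weight, kg.  Entry criteria restrict this to [50, 100].
    height : cm.
    age : years, within [18, 55].
    sex : ``"male"`` or ``"female"``.
    """

    subject_id: object
    weight: float
    height: float
    age: float
    sex: str

    def __post_init__(self) -> None:
        if not 50.0 <= self.weight <= 100.0:
            raise ValidationError(
                f"subject {self.subject_id}: weight {self.weight} kg outside [50, 100]"
            )
        if not 18.0 <= self.age <= 55.0:
            raise ValidationError(
                f"subject {self.subject_id}: age {self.age} outside [18, 55]"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(f"subject {self.subject_id}: sex must be male/female")
        if not 18.0 - 1e-9 <= self.bmi <= 26.0 + 1e-9:
            raise ValidationError(
                f"subject {self.subject_id}: BMI {self.bmi:.2f} outside [18, 26]"
            )

    @property
    def bmi(self) -> float:
        """Body-mass index, kg m^-2 (derived from weight and height)."""
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion (or bolus when ``duration`` is 0).

    ``start_time`` and ``duration`` in minutes, ``amount`` in mg.
    """

    start_time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValidationError("dose start_time must be non-negative")
        if self.amount < 0:
            raise ValidationError("dose amount must be non-negative")
        if self.duration < 0:
            raise ValidationError("dose duration must be non-negative")

    @property
    def rate(self) -> float | None:
        """Infusion rate in mg min^-1, or None for an instantaneous bolus."""
        if self.duration == 0:
            return None
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events for one subject."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        times = [e.start_time for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("regimen events must be sorted by start_time")

    @property
    def total_amount(self) -> float:
        return sum(e.amount for e in self.events)

    def scaled(self, factor: float) -> "Regimen":
        return Regimen(tuple(replace(e, amount=e.amount * factor) for e in self.events))


@dataclass(frozen=True)
class RegimenSpec:
    """Weight-based loading + maintenance infusion specification.

    Loading dose in mg kg^-1 delivered over ``loading_duration_min``;
    maintenance rate in mg kg^-1 h^-1 for ``maintenance_duration_min``.
    Either part may be omitted by setting its amount/rate to 0.
    """

    loading_mg_per_kg: float = 0.0
    loading_duration_min: float = 1.0
    maintenance_mg_per_kg_per_h: float = 0.0
    maintenance_duration_min: float = 0.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RegimenSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise SchemaError(f"unknown regimen keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: float(getattr(self, k)) for k in self.__dataclass_fields__}, fh
            )


def resolve_regimen(spec: RegimenSpec, cov: SubjectCovariates | float) -> Regimen:
    """Resolve a per-kg regimen specification to absolute-mg dose events.

    ``cov`` may be a :class:`SubjectCovariates` or a bare weight in kg.
    The maintenance infusion starts when the loading infusion ends, at a
    constant rate of ``maintenance_mg_per_kg_per_h * weight / 60`` mg min^-1.
    """
    weight = cov.weight if isinstance(cov, SubjectCovariates) else float(cov)
    if weight <= 0:
        raise ValidationError("weight must be positive")
    for name in spec.__dataclass_fields__:
        if getattr(spec, name) < 0:
            raise ValidationError(f"regimen spec field {name} must be non-negative")
    events = []
    t = 0.0
    if spec.loading_mg_per_kg > 0:
        events.append(
            DoseEvent(0.0, spec.loading_mg_per_kg * weight, spec.loading_duration_min)
        )
        t = spec.loading_duration_min
    if spec.maintenance_mg_per_kg_per_h > 0 and spec.maintenance_duration_min > 0:
        rate = spec.maintenance_mg_per_kg_per_h * weight / 60.0  # mg min^-1
        events.append(
            DoseEvent(t, rate * spec.maintenance_duration_min, spec.maintenance_duration_min)
        )
    return Regimen(tuple(events))


@dataclass(frozen=True)
class ObservationRecord:
    """One observation: plasma concentration, BIS, or MOAA/S score.

    ``bql`` flags concentrations below the assay LLOQ (0.5 ng mL^-1);
    such records are retained but excluded from likelihoods by default.
    """

    subject_id: object
    time: float
    dvid: int
    value: float
    bql: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("observation time must be non-negative")
        if self.dvid not in _DVID_NAMES:
            raise ValidationError(f"unknown DVID {self.dvid}")
        if self.dvid == DVID_MOAAS:
            if self.value != int(self.value) or not 0 <= self.value <= 5:
                raise ValidationError(
                    f"MOAA/S value {self.value!r} not an integer in 0..5"
                )
        if self.dvid == DVID_CONC and self.value < 0:
            raise ValidationError("concentration must be non-negative")


@dataclass
class ObservationTable:
    """Long-format trial dataset: covariates, dosing and observations."""

    covariates: dict
    doses: dict
    observations: list

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.subject_id not in self.covariates:
                raise ValidationError(f"no covariates for subject {obs.subject_id}")
            if obs.subject_id not in self.doses:
                raise ValidationError(f"no regimen for subject {obs.subject_id}")

    @property
    def subject_ids(self) -> list:
        return list(self.covariates)

    def records(self, dvid: int | None = None, subject_id=None) -> list:
        out = self.observations
        if dvid is not None:
            out = [o for o in out if o.dvid == dvid]
        if subject_id is not None:
            out = [o for o in out if o.subject_id == subject_id]
        return out

    def count(self, dvid: int) -> int:
        return sum(1 for o in self.observations if o.dvid == dvid)

    def equals(self, other: "ObservationTable", tol: float = 1e-9) -> bool:
        def close(a, b):
            return abs(a - b) <= tol * max(1.0, abs(a), abs(b))

        if set(self.covariates) != set(other.covariates):
            return False
        for sid, cov in self.covariates.items():
            oc = other.covariates[sid]
            if cov.sex != oc.sex:
                return False
            for f in ("weight", "height", "age"):
                if not close(getattr(cov, f), getattr(oc, f)):
                    return False
            mine, theirs = self.doses[sid].events, other.doses[sid].events
            if len(mine) != len(theirs):
                return False
            for a, b in zip(mine, theirs):
                if not all(
                    close(getattr(a, f), getattr(b, f))
                    for f in ("start_time", "amount", "duration")
                ):
                    return False
        if len(self.observations) != len(other.observations):
            return False
        order = {sid: i for i, sid in enumerate(self.subject_ids)}

        def key(o):
            return (order[o.subject_id], o.time, o.dvid, o.value)

        for a, b in zip(sorted(self.observations, key=key), sorted(other.observations, key=key)):
            if a.subject_id != b.subject_id or a.dvid != b.dvid or a.bql != b.bql:
                return False
            if not (close(a.time, b.time) and close(a.value, b.value)):
                return False
        return True


_REQUIRED = ["ID", "TIME", "AMT", "DV", "DVID", "MDV", "WT", "HT", "AGE", "SEX"]


def read_dataset(path: str | Path) -> ObservationTable:
    """Read an event-record CSV into an :class:`ObservationTable`.

    Required columns: ``ID, TIME, AMT, RATE`` (or ``DUR``), ``DV, DVID, MDV,
    WT, HT, AGE, SEX``; missing values are coded ``"."``.  Rows with
    ``AMT`` > 0 become dose events; rows with ``MDV`` = 0 become observations.
    Concentrations below the LLOQ are flagged ``bql``.
    """
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col}")
    if "RATE" not in df.columns and "DUR" not in df.columns:
        raise SchemaError("missing required column RATE (or DUR)")

    covariates: dict = {}
    doses: dict = {}
    observations: list = []
    for sid, grp in df.groupby("ID", sort=False):
        first = grp.iloc[0]
        covariates[sid] = SubjectCovariates(
            subject_id=sid,
            weight=float(first["WT"]),
            height=float(first["HT"]),
            age=float(first["AGE"]),
            sex="male" if int(first["SEX"]) == 1 else "female",
        )
        events = []
        for _, row in grp.iterrows():
            amt = 0.0 if pd.isna(row["AMT"]) else float(row["AMT"])
            if amt > 0:
                if "DUR" in df.columns and not pd.isna(row.get("DUR", np.nan)):
                    dur = float(row["DUR"])
                else:
                    rate = float(row["RATE"]) if not pd.isna(row["RATE"]) else 0.0
                    dur = amt / rate if rate > 0 else 0.0
                events.append(DoseEvent(float(row["TIME"]), amt, dur))
        doses[sid] = Regimen(tuple(sorted(events, key=lambda e: e.start_time)))
        for idx, row in grp.iterrows():
            amt = 0.0 if pd.isna(row["AMT"]) else float(row["AMT"])
            if amt > 0 or int(row["MDV"]) == 1:
                continue
            dvid = int(row["DVID"])
            value = float(row["DV"])
            if dvid == DVID_MOAAS and (value != int(value) or not 0 <= value <= 5):
                raise ValidationError(
                    f"row {idx}: MOAA/S value {value!r} outside {{0..5}}"
                )
            observations.append(
                ObservationRecord(
                    subject_id=sid,
                    time=float(row["TIME"]),
                    dvid=dvid,
                    value=value,
                    bql=(dvid == DVID_CONC and value < LLOQ),
                )
            )
    return ObservationTable(covariates, doses, observations)


def write_dataset(table: ObservationTable, path: str | Path) -> None:
    """Write a table as an event-record CSV readable by :func:`read_dataset`.

    Numeric fields are formatted with 12 significant digits so that a
    read/write round trip is the identity to well below 1e-9 relative.
    """
    rows = []
    sex_code = {"male": 1, "female": 0}

    def base(sid):
        cov = table.covariates[sid]
        return {
            "ID": sid,
            "WT": cov.weight,
            "HT": cov.height,
            "AGE": cov.age,
            "SEX": sex_code[cov.sex],
        }

    for sid in table.subject_ids:
        for ev in table.doses[sid].events:
            rate = ev.rate if ev.rate is not None else 0.0
            rows.append(
                base(sid)
                | {
                    "TIME": ev.start_time,
                    "AMT": ev.amount,
                    "RATE": rate,
                    "DV": np.nan,
                    "DVID": 0,
                    "MDV": 1,
                }
            )
    for obs in table.observations:
        rows.append(
            base(obs.subject_id)
            | {
                "TIME": obs.time,
                "AMT": np.nan,
                "RATE": np.nan,
                "DV": obs.value,
                "DVID": obs.dvid,
                "MDV": 0,
            }
        )
    cols = ["ID", "TIME", "AMT", "RATE", "DV", "DVID", "MDV", "WT", "HT", "AGE", "SEX"]
    df = pd.DataFrame(rows, columns=cols)
    # stable NONMEM-ish ordering: subject, then time, dose rows before obs at ties
    order = {sid: i for i, sid in enumerate(table.subject_ids)}
    df = df.sort_values(
        by=["ID", "TIME", "MDV"],
        key=lambda s: s.map(order) if s.name == "ID" else s,
        ascending=[True, True, False],
        kind="stable",
    )
    df.to_csv(path, index=False, na_rep=".", float_format="%.17g")
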