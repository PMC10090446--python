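"""Subject/cohort domain types and event-record table I/O.

The on-disk format is a NONMEM/Pmetrics-style event-record CSV: one row per
dose or observation, with per-subject covariates repeated on every row of
that subject.  Columns: ``id, time, dose_amt, dose_dur, conc, age, wt, sex,
scr, alb, apache2``.  Empty cells mean "not applicable" (a dose row has an
empty ``conc``; an observation row has empty ``dose_amt``/``dose_dur``).

Times are hours since each subject's first dose.  Concentrations are total
polymyxin B in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LLOQ",
    "DoseEvent",
    "Observation",
    "CovariateSet",
    "Subject",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

#: Default lower limit of quantification for total drug, mg/L (assay limit
#: of the dominant B1 component).
DEFAULT_LLOQ = 0.19

_COLUMNS = ["id", "time", "dose_amt", "dose_dur", "conc",
            "age", "wt", "sex", "scr", "alb", "apache2"]
_REQUIRED = ["id", "time", "dose_amt", "dose_dur", "conc"]


class CohortFormatError(ValueError):
    """Raised when an event-record file is structurally malformed."""


class CohortValidationError(ValueError):
    """Raised when a parsed cohort violates a domain invariant."""


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous infusion: start ``time`` (h), ``amount`` (mg),
    ``duration`` (h).  ``rate`` (mg/h) is derived."""

    time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise CohortValidationError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise CohortValidationError(f"dose amount must be >= 0, got {self.amount}")
        if not self.duration > 0:
            raise CohortValidationError(
                f"infusion duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.time + self.duration


@dataclass(frozen=True)
class Observation:
    """A measured total polymyxin B concentration at ``time`` h.

    ``blq`` flags observations below the limit of quantification; those are
    excluded from all likelihood computations by default.
    """

    time: float
    concentration: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise CohortValidationError(
                f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise CohortValidationError(
                f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class CovariateSet:
    """Baseline covariates for one patient.

    age in years, weight in kg, serum creatinine (scr) in µmol/L, albumin
    (alb) in g/L, apache2 the APACHE-II severity score.  ``sex`` is "M"/"F".
    Creatinine clearance (``ccr``, mL/min) is derived by Cockcroft–Gault.
    """

    age: float
    wt: float
    sex: str
    scr: float
    alb: float
    apache2: float

    def __post_init__(self) -> None:
        for name in ("age", "wt", "scr", "alb", "apache2"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise CohortValidationError(f"covariate {name} must be > 0, got {v}")
        if self.sex not in ("M", "F"):
            raise CohortValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")

    @property
    def ccr(self) -> float:
        """Cockcroft–Gault creatinine clearance, mL/min."""
        from .covariates import cockcroft_gault
        return cockcroft_gault(self.age, self.wt, self.scr, self.sex)

    def as_dict(self) -> dict[str, float | str]:
        return {"age": self.age, "wt": self.wt, "sex": self.sex,
                "scr": self.scr, "alb": self.alb, "apache2": self.apache2}


@dataclass
class Subject:
    """One patient: dosing history, observations and covariates.

    Doses and observations are kept sorted by time; at least one dose must
    precede the first observation.
    """

    id: str
    covariates: CovariateSet | None
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.time)
        self.observations = sorted(self.observations, key=lambda o: o.time)
        if self.observations:
            if not self.doses:
                raise CohortValidationError(
                    f"subject {self.id!r}: observations without any dose")
            if self.observations[0].time < self.doses[0].time:
                raise CohortValidationError(
                    f"subject {self.id!r}: first observation at "
                    f"t={self.observations[0].time} precedes first dose at "
                    f"t={self.doses[0].time}")

    @property
    def obs_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def obs_conc(self) -> np.ndarray:
        return np.array([o.concentration for o in self.observations], dtype=float)

    def quantified(self) -> "Subject":
        """Copy of this subject with BLQ observations removed."""
        return replace(self, observations=[o for o in self.observations if not o.blq])


@dataclass
class Cohort:
    """A list of subjects with unique ids."""

    subjects: list[Subject]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        """Total observation count across subjects (BLQ included)."""
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_obs_quantified(self) -> int:
        return sum(sum(not o.blq for o in s.observations) for s in self.subjects)


def read_cohort(path, lloq: float = DEFAULT_LLOQ) -> Cohort:
    """Read an event-record CSV into a :class:`Cohort`.

    Rows with ``dose_amt > 0`` become :class:`DoseEvent`; rows with a
    non-missing ``conc`` become :class:`Observation` (``conc < lloq`` sets
    the BLQ flag).  Covariate columns are optional; when present they must
    be constant within a subject (the first non-missing row is used).
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {missing}")
    has_cov = all(c in df.columns for c in ("age", "wt", "sex", "scr", "alb", "apache2"))

    subjects = []
    for sid, grp in df.groupby("id", sort=False):
        times = grp["time"].to_numpy(dtype=float)
        if np.any(times < 0):
            raise CohortValidationError(f"subject {sid!r}: negative event time")
        if np.any(np.diff(times) < 0):
            raise CohortValidationError(
                f"subject {sid!r}: event times not non-decreasing")
        doses, obs = [], []
        for _, row in grp.iterrows():
            amt = row["dose_amt"]
            if pd.notna(amt) and float(amt) > 0:
                doses.append(DoseEvent(float(row["time"]), float(amt),
                                       float(row["dose_dur"])))
            conc = row["conc"]
            if pd.notna(conc):
                c = float(conc)
                obs.append(Observation(float(row["time"]), c, blq=c < lloq))
        cov = None
        if has_cov:
            first = grp.dropna(subset=["age"]).iloc[0] if grp["age"].notna().any() else None
            if first is not None:
                cov = CovariateSet(age=float(first["age"]), wt=float(first["wt"]),
                                   sex=str(first["sex"]), scr=float(first["scr"]),
                                   alb=float(first["alb"]),
                                   apache2=float(first["apache2"]))
        subjects.append(Subject(id=str(sid), covariates=cov, doses=doses,
                                observations=obs))
    return Cohort(subjects)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as an event-record CSV re-readable by :func:`read_cohort`.

    Column order is fixed; floats carry enough digits for an exact
    round-trip (pandas writes full repr precision).
    """
    rows = []
    for s in cohort:
        cov = s.covariates.as_dict() if s.covariates else {}
        events = ([("dose", d.time, d) for d in s.doses]
                  + [("obs", o.time, o) for o in s.observations])
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, t, ev in events:
            row = {"id": s.id, "time": t, "dose_amt": None, "dose_dur": None,
                   "conc": None, **cov}
            if kind == "dose":
                row["dose_amt"] = ev.amount
                row["dose_dur"] = ev.duration
            else:
                row["conc"] = ev.concentration
            rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
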