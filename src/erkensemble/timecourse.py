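"""Time-course data model and CSV I/O.

The experimental design this package targets is a quantified immunoblot
time course: phospho-protein readouts (pMEK, pERK), normalized by total
ERK, measured at a handful of stimulation times for a small factorial of
conditions (ligand dose x drug treatment), summarized as replicate
mean +/- SEM.

The on-disk representation is a flat CSV with one row per
(readout, condition, time) summary point::

    readout,dose,treatment,time_min,mean,sem,n_reps

``treatment`` is ``control`` (vehicle) or ``inhibited`` (proteasome
inhibitor).  An empty ``sem`` field is permitted only for single-replicate
points and is read as 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "TREATMENTS",
    "READOUTS",
    "Condition",
    "TimeCoursePoint",
    "TimeCourseDataset",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

TREATMENTS = ("control", "inhibited")
READOUTS = ("pMEK", "pERK")

CSV_COLUMNS = ["readout", "dose", "treatment", "time_min", "mean", "sem", "n_reps"]


@dataclass(frozen=True, order=True)
class Condition:
    """One experimental arm: a ligand dose label crossed with a treatment.

    ``dose_label`` is a free-form label ("low"/"high", "0.03 nM", ...);
    ``treatment`` must be one of :data:`TREATMENTS`.
    """

    dose_label: str
    treatment: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )

    @property
    def key(self) -> str:
        return f"{self.dose_label}/{self.treatment}"


@dataclass(frozen=True)
class TimeCoursePoint:
    """One summary measurement: replicate mean +/- SEM at a single time."""

    readout: str
    condition: Condition
    time: float
    mean: float
    sem: float
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.readout not in READOUTS:
            raise ValidationError(
                f"readout must be one of {READOUTS}, got {self.readout!r}"
            )
        for name in ("time", "mean", "sem"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value!r}")
        if self.n_reps < 1:
            raise ValidationError(f"n_reps must be >= 1, got {self.n_reps!r}")


class TimeCourseDataset:
    """An immutable, validated collection of time-course points.

    Invariants enforced at construction:

    * ``(readout, condition, time)`` triples are unique;
    * every time course includes a ``t = 0`` (pre-stimulation) point —
      the ODE stage anchors its initial condition there;
    * every condition measured for pERK also carries a pMEK course whose
      time grid covers the pERK times, because the ERK model needs a
      fitted MEK input for that condition.
    """

    def __init__(self, points: Iterable[TimeCoursePoint]):
        pts = tuple(points)
        seen: dict[tuple, TimeCoursePoint] = {}
        for p in pts:
            key = (p.readout, p.condition, p.time)
            if key in seen:
                raise ValidationError(
                    f"duplicate (readout, condition, time) triple: "
                    f"{p.readout}, {p.condition.key}, t={p.time}"
                )
            seen[key] = p
        self._points = tuple(
            sorted(pts, key=lambda p: (p.readout, p.condition, p.time))
        )
        self._validate_structure()

    # -- structure ---------------------------------------------------------

    def _validate_structure(self) -> None:
        courses: dict[tuple[str, Condition], set[float]] = {}
        for p in self._points:
            courses.setdefault((p.readout, p.condition), set()).add(p.time)
        for (readout, cond), times in courses.items():
            if 0.0 not in times:
                raise ValidationError(
                    f"time course {readout} @ {cond.key} lacks a t=0 baseline point"
                )
        for (readout, cond), times in courses.items():
            if readout != "pERK":
                continue
            mek_times = courses.get(("pMEK", cond))
            if mek_times is None or not times <= mek_times:
                raise ValidationError(
                    f"pERK course for condition {cond.key} has no covering "
                    f"pMEK course (the ERK model requires a fitted MEK input)"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def points(self) -> tuple[TimeCoursePoint, ...]:
        return self._points

    @property
    def time_grid(self) -> np.ndarray:
        return np.array(sorted({p.time for p in self._points}))

    @property
    def conditions(self) -> frozenset[Condition]:
        return frozenset(p.condition for p in self._points)

    @property
    def readouts(self) -> frozenset[str]:
        return frozenset(p.readout for p in self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeCourseDataset):
            return NotImplemented
        return self._points == other._points

    def __hash__(self):
        return hash(self._points)

    def conditions_with(self, readout: str) -> list[Condition]:
        """Conditions carrying a time course for ``readout``, sorted."""
        return sorted({p.condition for p in self._points if p.readout == readout})

    def course(
        self, readout: str, condition: Condition
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(times, means, sems, n_reps)`` sorted by time."""
        sel = [
            p
            for p in self._points
            if p.readout == readout and p.condition == condition
        ]
        sel.sort(key=lambda p: p.time)
        times = np.array([p.time for p in sel])
        means = np.array([p.mean for p in sel])
        sems = np.array([p.sem for p in sel])
        n_reps = np.array([p.n_reps for p in sel])
        return times, means, sems, n_reps

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "readout": p.readout,
                "dose": p.condition.dose_label,
                "treatment": p.condition.treatment,
                "time_min": p.time,
                "mean": p.mean,
                "sem": p.sem,
                "n_reps": p.n_reps,
            }
            for p in self._points
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _points_from_frame(df: pd.DataFrame) -> list[TimeCoursePoint]:
    points = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header row
        sem = row["sem"]
        n_reps = row["n_reps"]
        if pd.isna(n_reps):
            raise ValidationError(f"row {rowno}: missing n_reps")
        n_reps = int(n_reps)
        if pd.isna(sem):
            if n_reps != 1:
                raise ValidationError(
                    f"row {rowno}: missing sem is only allowed when n_reps = 1"
                )
            sem = 0.0
        try:
            point = TimeCoursePoint(
                readout=str(row["readout"]),
                condition=Condition(str(row["dose"]), str(row["treatment"])),
                time=float(row["time_min"]),
                mean=float(row["mean"]),
                sem=float(sem),
                n_reps=n_reps,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {rowno}: {exc}") from None
        points.append(point)
    return points


def read_timecourse_csv(path) -> TimeCourseDataset:
    """Read and validate a time-course CSV (schema in the module docstring).

    Raises :class:`SchemaError` when a column is missing and
    :class:`ValidationError` (with the offending row number) when a value
    violates an invariant.
    """
    df = pd.read_csv(
        path,
        dtype={"readout": str, "dose": str, "treatment": str},
        float_precision="round_trip",  # exact CSV round-trip contract
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    return TimeCourseDataset(_points_from_frame(df[CSV_COLUMNS]))


def write_timecourse_csv(dataset: TimeCourseDataset, path) -> None:
    """Write a dataset to CSV, losslessly (17 significant digits).

    Round-trip identity: ``read_timecourse_csv`` of the written file
    reproduces ``dataset`` exactly for all finite values.
    """
    df = dataset.to_frame()
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def dataset_from_arrays(
    courses: Mapping[tuple[str, Condition], tuple],
) -> TimeCourseDataset:
    """Convenience constructor from ``{(readout, cond): (t, mean, sem, n)}``."""
    points = []
    for (readout, cond), (times, means, sems, n_reps) in courses.items():
        n_arr = np.broadcast_to(np.asarray(n_reps), np.shape(times))
        for t, m, s, n in zip(times, means, sems, n_arr):
            points.append(
                TimeCoursePoint(readout, cond, float(t), float(m), float(s), int(n))
            )
    return TimeCourseDataset(points)
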