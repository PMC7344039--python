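"""Cohort filtering and temporal resampling of irregular ICU measurements.

Raw charted measurements arrive as irregular (time, value) points per feature
per admission. Each feature series is fitted with a support-vector regression
of value on time and evaluated on a regular 10-minute grid spanning the
admission, which yields the fixed-frequency state matrix the decision models
consume.

Admissions ventilated for less than 24 hours, or not discharged alive from
the ICU, are excluded from the cohort before resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

__all__ = [
    "RawMeasurementSeries",
    "AdmissionRecord",
    "SvrConfig",
    "filter_admissions",
    "resample_series",
    "resample_admission",
    "one_hot",
    "one_hot_decode",
]


@dataclass
class RawMeasurementSeries:
    """Irregular measurements of one feature during one admission.

    ``points`` is a list of ``(t_minutes, value)`` with non-negative, sorted
    timestamps (minutes since admission).
    """

    admission_id: str
    feature_name: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(t < 0 for t in times):
            raise ValueError(
                f"negative timestamp in series {self.feature_name!r} "
                f"of admission {self.admission_id!r}"
            )
        if times != sorted(times):
            raise ValueError(
                f"timestamps not sorted in series {self.feature_name!r} "
                f"of admission {self.admission_id!r}"
            )


@dataclass
class AdmissionRecord:
    """One ICU admission with its raw measurement series and cohort metadata."""

    admission_id: str
    admit_time: float
    discharge_time: float
    ventilation_hours: float
    discharged_alive: bool
    series: list[RawMeasurementSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.discharge_time <= self.admit_time:
            raise ValueError(
                f"admission {self.admission_id!r}: discharge must follow admission"
            )

    @property
    def duration_minutes(self) -> float:
        return self.discharge_time - self.admit_time


@dataclass(frozen=True)
class SvrConfig:
    """Hyperparameters of the per-feature support-vector regression.

    Defaults: radial-basis kernel, C=100, epsilon-tube 0.01, gamma='scale'.
    These are logged with every run so the resampling is reproducible.
    """

    kernel: str = "rbf"
    C: float = 100.0
    epsilon: float = 0.01
    gamma: str | float = "scale"


def filter_admissions(records: Sequence[AdmissionRecord]) -> list[AdmissionRecord]:
    """Apply the cohort exclusion rules, preserving input order.

    Keeps exactly the admissions ventilated for at least 24 hours AND
    discharged alive from the ICU.
    """
    kept = []
    for rec in records:
        if rec.ventilation_hours is None or rec.discharged_alive is None:
            raise ValueError(f"admission {rec.admission_id!r} is missing cohort fields")
        if rec.ventilation_hours >= 24.0 and rec.discharged_alive:
            kept.append(rec)
    return kept


def resample_series(
    series: RawMeasurementSeries,
    step: float = 10.0,
    svr_cfg: SvrConfig | None = None,
    t_end: float | None = None,
) -> list[tuple[float, float]]:
    """Fit an SVR of value on time and evaluate it on the regular grid.

    The grid is {0, step, 2*step, ...} up to ``t_end`` (inclusive); ``t_end``
    defaults to the last observation time. Grid points beyond the last
    observation take the regression's own prediction — no separate
    extrapolation rule. A series with fewer than 2 points falls back to a
    constant fill (with a warning).
    """
    svr_cfg = svr_cfg or SvrConfig()
    if t_end is None:
        if not series.points:
            raise ValueError(f"empty series {series.feature_name!r}")
        t_end = series.points[-1][0]
    grid = np.arange(0.0, t_end + step / 2, step)

    if len(series.points) < 2:
        warnings.warn(
            f"series {series.feature_name!r} of admission {series.admission_id!r} "
            "has fewer than 2 points; using constant fill",
            stacklevel=2,
        )
        value = series.points[0][1] if series.points else float("nan")
        return [(float(t), float(value)) for t in grid]

    t = np.array([p[0] for p in series.points], dtype=np.float64).reshape(-1, 1)
    v = np.array([p[1] for p in series.points], dtype=np.float64)
    model = SVR(kernel=svr_cfg.kernel, C=svr_cfg.C, epsilon=svr_cfg.epsilon, gamma=svr_cfg.gamma)
    model.fit(t, v)
    pred = model.predict(grid.reshape(-1, 1))
    return [(float(t_), float(p)) for t_, p in zip(grid, pred)]


def resample_admission(
    record: AdmissionRecord,
    step: float = 10.0,
    svr_cfg: SvrConfig | None = None,
) -> pd.DataFrame:
    """Resample every feature series of an admission onto one shared grid.

    Returns a DataFrame indexed by ``t_index`` (grid step number) with one
    column per feature, spanning admission to discharge.
    """
    duration = record.duration_minutes
    out: dict[str, list[float]] = {}
    n = None
    for series in record.series:
        pairs = resample_series(series, step=step, svr_cfg=svr_cfg, t_end=duration)
        out[series.feature_name] = [v for _, v in pairs]
        n = len(pairs)
    df = pd.DataFrame(out)
    df.index.name = "t_index"
    df.insert(0, "admission_id", record.admission_id)
    if n is not None:
        df.index = np.arange(n)
        df.index.name = "t_index"
    return df


def one_hot(labels: Sequence, vocabulary: Sequence) -> np.ndarray:
    """One-hot encode ``labels`` against an ordered ``vocabulary``.

    Each row has exactly one active bit, at the label's vocabulary index.
    """
    index = {cat: i for i, cat in enumerate(vocabulary)}
    mat = np.zeros((len(labels), len(vocabulary)), dtype=np.float64)
    for row, label in enumerate(labels):
        if label not in index:
            raise KeyError(f"label {label!r} not in vocabulary")
        mat[row, index[label]] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray, vocabulary: Sequence) -> list:
    """Inverse of :func:`one_hot` (argmax per row)."""
    matrix = np.asarray(matrix)
    return [vocabulary[int(i)] for i in np.argmax(matrix, axis=1)]


def read_raw_measurements_csv(path) -> dict[str, list[RawMeasurementSeries]]:
    """Read the `admission_id,feature_name,t_minutes,value` CSV into series."""
    df = pd.read_csv(path, dtype={"admission_id": str})
    out: dict[str, list[RawMeasurementSeries]] = {}
    for (adm, feat), grp in df.groupby(["admission_id", "feature_name"], sort=False):
        grp = grp.sort_values("t_minutes")
        out.setdefault(adm, []).append(
            RawMeasurementSeries(
                admission_id=adm,
                feature_name=feat,
                points=list(zip(grp["t_minutes"].astype(float), grp["value"].astype(float))),
            )
        )
    return out


def read_admissions_csv(path, series_by_admission=None) -> list[AdmissionRecord]:
    """Read the `admission_id,admit,discharge,vent_hours,discharged_alive` CSV."""
    df = pd.read_csv(path, dtype={"admission_id": str})
    series_by_admission = series_by_admission or {}
    records = []
    for row in df.itertuples():
        records.append(
            AdmissionRecord(
                admission_id=row.admission_id,
                admit_time=float(row.admit),
                discharge_time=float(row.discharge),
                ventilation_hours=float(row.vent_hours),
                discharged_alive=bool(int(row.discharged_alive)),
                series=series_by_admission.get(row.admission_id, []),
            )
        )
    return records
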