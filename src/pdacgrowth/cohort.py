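"""Domain types for serial pancreatic-lesion cohorts, unit conventions, and CSV I/O.

A cohort holds one record per patient: serial biaxial lesion measurements
from contrast CT (long/short axis in mm), an imaging subtype label
(high/low delta), and optionally serial body-composition and blood-glucose
series collected in the pre-diagnostic window.

Unit conventions
----------------
Lesion volumes are internal mm^3 (the single-cell and detectable-mass
thresholds used for initiation-time projection are stated in mm^3);
report-facing volumes are cm^3 (1 cm^3 = 1000 mm^3). Time is months;
calendar dates are converted at 30.4375 days/month. Each patient's time
origin is their first scan.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MM3_PER_CM3 = 1000.0
DAYS_PER_MONTH = 30.4375

#: Tissue compartments quantified on the single L2-L3 axial slice.
TISSUES = ("SAF", "VAF", "muscle")


class InvalidMeasurementError(ValueError):
    """A physically impossible measurement (non-positive axis, diameter...)."""


class SchemaError(ValueError):
    """Input table violates the cohort CSV schema."""


class DeltaClass(str, enum.Enum):
    """Imaging-based subtype from tumor-parenchyma interface conspicuity."""

    HIGH = "high"
    LOW = "low"

    @classmethod
    def coerce(cls, value: "DeltaClass | str") -> "DeltaClass":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise SchemaError(f"unknown delta class {value!r}; expected 'high' or 'low'") from None


def mean_diameter(long_axis: float, short_axis: float) -> float:
    """Geometric mean of the biaxial measurements, mm.

    The geometric mean of the long and short axes approximates the mean
    lesion diameter of an ellipsoidal lesion measured in-plane.
    """
    if long_axis <= 0 or short_axis <= 0:
        raise InvalidMeasurementError(
            f"axes must be positive, got long={long_axis}, short={short_axis}"
        )
    return math.sqrt(long_axis * short_axis)


def sphere_volume(diameter: float) -> float:
    """Volume (mm^3) of a sphere with the given diameter (mm): pi d^3 / 6."""
    if diameter < 0:
        raise InvalidMeasurementError(f"diameter must be non-negative, got {diameter}")
    return math.pi * diameter**3 / 6.0


@dataclass(frozen=True)
class LesionObservation:
    """One scan's biaxial lesion measurement.

    time is months since the patient's first observation (first scan is
    exactly 0); axes are mm with short_axis <= long_axis.
    """

    time: float
    long_axis: float
    short_axis: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidMeasurementError(f"time must be non-negative, got {self.time}")
        if self.long_axis <= 0 or self.short_axis <= 0:
            raise InvalidMeasurementError("axes must be positive")
        if self.short_axis > self.long_axis + 1e-12:
            raise InvalidMeasurementError(
                f"short axis {self.short_axis} exceeds long axis {self.long_axis}"
            )

    @property
    def diameter(self) -> float:
        """Mean lesion diameter, mm."""
        return mean_diameter(self.long_axis, self.short_axis)

    @property
    def volume_mm3(self) -> float:
        """Spherical-approximation lesion volume, mm^3."""
        return sphere_volume(self.diameter)


@dataclass(frozen=True)
class TimeSeries:
    """Serial values on a time axis in months relative to diagnosis (<= 0)."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise SchemaError("times and values must have equal length")
        t = np.asarray(self.times, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise SchemaError("times must be strictly increasing")
        if np.any(np.asarray(self.values, dtype=float) <= 0):
            raise SchemaError("series values must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class PatientRecord:
    """All serial data for one patient.

    observations are ordered lesion measurements ending at the diagnostic
    scan; tissue_series maps SAF/VAF/muscle to volume series (cm^3);
    bg_series is blood glucose (mg/dL).
    """

    patient_id: str
    delta_class: DeltaClass
    observations: Sequence[LesionObservation]
    tissue_series: Mapping[str, TimeSeries] | None = None
    bg_series: TimeSeries | None = None

    def __post_init__(self) -> None:
        self.delta_class = DeltaClass.coerce(self.delta_class)
        obs = list(self.observations)
        if len(obs) < 2:
            raise SchemaError(
                f"patient {self.patient_id}: need >=2 observations, got {len(obs)}"
            )
        times = [o.time for o in obs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise SchemaError(f"patient {self.patient_id}: times must be strictly increasing")
        if abs(times[0]) > 1e-12:
            raise SchemaError(f"patient {self.patient_id}: first observation time must be 0")
        self.observations = tuple(obs)
        if self.tissue_series is not None:
            bad = set(self.tissue_series) - set(TISSUES)
            if bad:
                raise SchemaError(f"patient {self.patient_id}: unknown tissue(s) {sorted(bad)}")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    @property
    def volumes_mm3(self) -> np.ndarray:
        return np.array([o.volume_mm3 for o in self.observations])


@dataclass
class Cohort:
    """A de-identified patient collection plus provenance metadata."""

    patients: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patients:
            raise SchemaError("cohort must be non-empty")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def classes(self) -> set[DeltaClass]:
        return {p.delta_class for p in self.patients}

    def by_class(self, delta_class: DeltaClass | str) -> list[PatientRecord]:
        dc = DeltaClass.coerce(delta_class)
        return [p for p in self.patients if p.delta_class == dc]


# ---------------------------------------------------------------------------
# CSV I/O
#
# lesions CSV: patient_id, delta_class, scan_time_months | scan_date,
#              long_axis_mm, short_axis_mm
# tissue CSV:  patient_id, tissue, time_months_rel_dx,
#              area_cm2 + slice_thickness_mm | volume_cm3
# bg CSV:      patient_id, time_months_rel_dx, glucose_mg_dl
# ---------------------------------------------------------------------------

_LESION_COLS = {"patient_id", "delta_class", "long_axis_mm", "short_axis_mm"}


def _require_columns(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise SchemaError(f"{what} CSV missing column(s): {sorted(missing)}")


def _lesion_times_months(group: pd.DataFrame, patient_id: str) -> np.ndarray:
    if "scan_time_months" in group.columns and group["scan_time_months"].notna().all():
        return group["scan_time_months"].to_numpy(dtype=float)
    if "scan_date" in group.columns:
        dates = pd.to_datetime(group["scan_date"], format="ISO8601")
        days = (dates - dates.iloc[0]).dt.total_seconds() / 86400.0
        return days.to_numpy() / DAYS_PER_MONTH
    raise SchemaError(
        f"patient {patient_id}: need scan_time_months or scan_date column"
    )


def _collapse_duplicate_scans(times: np.ndarray, axes: np.ndarray, patient_id: str):
    """Average axes of rows that share a timestamp (one measurement per scan)."""
    uniq, inverse = np.unique(np.round(times, 9), return_inverse=True)
    if len(uniq) == len(times):
        return times, axes
    logger.warning(
        "patient %s: %d duplicate scan timestamp(s); averaging axes",
        patient_id, len(times) - len(uniq),
    )
    out = np.empty((len(uniq), axes.shape[1]))
    for i in range(len(uniq)):
        out[i] = axes[inverse == i].mean(axis=0)
    return uniq, out


def read_cohort(
    lesions_path,
    tissue_path=None,
    bg_path=None,
    metadata: dict | None = None,
) -> Cohort:
    """Load a cohort from the lesions CSV and optional tissue/BG CSVs.

    Lesion times are re-expressed relative to each patient's first scan.
    Raises SchemaError naming the offending patient for malformed input.
    """
    df = pd.read_csv(lesions_path, float_precision="round_trip")
    _require_columns(df, _LESION_COLS, "lesions")

    tissue_map: dict[str, dict[str, TimeSeries]] = {}
    if tissue_path is not None:
        tdf = pd.read_csv(tissue_path, float_precision="round_trip")
        _require_columns(tdf, {"patient_id", "tissue", "time_months_rel_dx"}, "tissue")
        if "volume_cm3" not in tdf.columns:
            _require_columns(tdf, {"area_cm2", "slice_thickness_mm"}, "tissue")
            tdf = tdf.assign(
                volume_cm3=tdf["area_cm2"] * tdf["slice_thickness_mm"] / 10.0
            )
        for (pid, tissue), g in tdf.groupby(["patient_id", "tissue"], sort=False):
            g = g.sort_values("time_months_rel_dx")
            tissue_map.setdefault(str(pid), {})[str(tissue)] = TimeSeries(
                tuple(g["time_months_rel_dx"].astype(float)),
                tuple(g["volume_cm3"].astype(float)),
            )

    bg_map: dict[str, TimeSeries] = {}
    if bg_path is not None:
        bdf = pd.read_csv(bg_path, float_precision="round_trip")
        _require_columns(bdf, {"patient_id", "time_months_rel_dx", "glucose_mg_dl"}, "bg")
        for pid, g in bdf.groupby("patient_id", sort=False):
            g = g.sort_values("time_months_rel_dx")
            bg_map[str(pid)] = TimeSeries(
                tuple(g["time_months_rel_dx"].astype(float)),
                tuple(g["glucose_mg_dl"].astype(float)),
            )

    patients = []
    for pid, group in df.groupby("patient_id", sort=False):
        pid = str(pid)
        if len(group) < 2:
            raise SchemaError(f"patient {pid}: need >=2 observations, got {len(group)}")
        times = _lesion_times_months(group, pid)
        order = np.argsort(times, kind="stable")
        times = times[order]
        axes = group[["long_axis_mm", "short_axis_mm"]].to_numpy(dtype=float)[order]
        times, axes = _collapse_duplicate_scans(times, axes, pid)
        if len(times) < 2:
            raise SchemaError(f"patient {pid}: <2 distinct scan times after averaging")
        times = times - times[0]
        dclass = DeltaClass.coerce(group["delta_class"].iloc[0])
        obs = [
            LesionObservation(float(t), float(la), float(sa))
            for t, (la, sa) in zip(times, axes)
        ]
        patients.append(
            PatientRecord(
                patient_id=pid,
                delta_class=dclass,
                observations=obs,
                tissue_series=tissue_map.get(pid) or None,
                bg_series=bg_map.get(pid),
            )
        )
    meta = dict(metadata or {})
    meta.setdefault("source", str(lesions_path))
    return Cohort(patients=patients, metadata=meta)


def write_cohort(cohort: Cohort, lesions_path, tissue_path=None, bg_path=None) -> None:
    """Write a cohort back to the CSV schemas (full float precision).

    write-then-read reproduces all numeric fields exactly (repr round-trip).
    """
    rows = [
        {
            "patient_id": p.patient_id,
            "delta_class": p.delta_class.value,
            "scan_time_months": repr(float(o.time)),
            "long_axis_mm": repr(float(o.long_axis)),
            "short_axis_mm": repr(float(o.short_axis)),
        }
        for p in cohort
        for o in p.observations
    ]
    pd.DataFrame(rows).to_csv(lesions_path, index=False)

    if tissue_path is not None:
        trows = [
            {
                "patient_id": p.patient_id,
                "tissue": tissue,
                "time_months_rel_dx": repr(float(t)),
                "volume_cm3": repr(float(v)),
            }
            for p in cohort
            if p.tissue_series
            for tissue, series in p.tissue_series.items()
            for t, v in zip(series.times, series.values)
        ]
        pd.DataFrame(
            trows, columns=["patient_id", "tissue", "time_months_rel_dx", "volume_cm3"]
        ).to_csv(tissue_path, index=False)

    if bg_path is not None:
        brows = [
            {
                "patient_id": p.patient_id,
                "time_months_rel_dx": repr(float(t)),
                "glucose_mg_dl": repr(float(v)),
            }
            for p in cohort
            if p.bg_series is not None
            for t, v in zip(p.bg_series.times, p.bg_series.values)
        ]
        pd.DataFrame(
            brows, columns=["patient_id", "time_months_rel_dx", "glucose_mg_dl"]
        ).to_csv(bg_path, index=False)
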