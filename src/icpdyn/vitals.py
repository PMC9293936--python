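"""Data model and preprocessing for ICP/MAP/CPP minute-resolution time series.

Severe traumatic-brain-injury patients in the ICU are monitored invasively:
intracranial pressure (ICP) and mean arterial pressure (MAP) are stored as
1-to-5-minute median values, from which cerebral perfusion pressure
(CPP = MAP - ICP) is derived.  This module provides the in-memory containers
for those series and the preprocessing contract applied before any feature is
computed:

* timestamps rounded to the nearest whole minute (half-up), duplicates on a
  minute collapsed to their median;
* physiologically impossible values removed with strict thresholds
  (ICP > 100 or < 0 mmHg; MAP > 150 or < 20 mmHg); boundary values are kept;
* CPP derived minute-wise on the intersection of the filtered ICP and MAP
  grids -- never filtered directly;
* data truncated to the first 120 h of monitoring;
* missing minutes left missing (no imputation, ever).

Time is integer minutes since ICU admission; all windows elsewhere in the
package are half-open ``[a, b)`` in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: signals that may appear in input files; CPP is derived, never ingested
SIGNALS = ("icp", "map", "cpp")

#: strict extreme-value exclusion thresholds, mmHg
EXTREME_LIMITS = {"icp": (0.0, 100.0), "map": (20.0, 150.0)}

#: monitoring horizon (hours) and eligibility span (hours)
HORIZON_H = 120.0
MIN_SPAN_H = 24.0
ADULT_AGE_YEARS = 16.0


class PreprocessingError(ValueError):
    """Raised when a preprocessing contract is violated."""


@dataclass(frozen=True)
class VitalsSeries:
    """One signal's minute-stamped sparse measurement sequence for one patient.

    Parameters
    ----------
    signal : {"icp", "map", "cpp"}
    times : ndarray of int
        Minutes since ICU admission, strictly increasing, at most one sample
        per minute.  Gaps (missing minutes) are allowed and preserved.
    values : ndarray of float
        Pressure in mmHg, same length as ``times``.
    """

    signal: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-d and equal length")
        if times.size and (np.any(np.diff(times) <= 0) or times[0] < 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span_min(self) -> int:
        """Last sample time in minutes, or 0 for an empty series."""
        return int(self.times[-1]) if len(self) else 0

    def slice_window(self, a_min: float, b_min: float) -> np.ndarray:
        """Values with times in the half-open window ``[a_min, b_min)``."""
        lo, hi = np.searchsorted(self.times, [a_min, b_min], side="left")
        return self.values[lo:hi]


def round_and_deduplicate(
    raw_samples: Iterable[tuple[float, float]], signal: str = "icp"
) -> VitalsSeries:
    """Round raw (time-in-seconds, value) samples to the minute grid.

    Times are rounded half-up to the nearest whole minute; samples landing on
    the same minute are collapsed to their median, mirroring how bedside
    systems store 1-to-5-minute median values.  The result is sorted and
    strictly increasing in time; an empty input yields an empty series.
    """
    raw = list(raw_samples)
    if not raw:
        return VitalsSeries(signal, np.array([], dtype=np.int64), np.array([]))
    secs = np.asarray([t for t, _ in raw], dtype=np.float64)
    vals = np.asarray([v for _, v in raw], dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise PreprocessingError("raw sample values must be finite")
    # round-half-up on the minute scale
    minutes = np.floor(secs / 60.0 + 0.5).astype(np.int64)
    if np.any(minutes < 0):
        raise PreprocessingError("negative sample times are not allowed")
    order = np.argsort(minutes, kind="stable")
    minutes, vals = minutes[order], vals[order]
    uniq, start = np.unique(minutes, return_index=True)
    bounds = np.append(start, minutes.size)
    med = np.array([np.median(vals[a:b]) for a, b in zip(bounds[:-1], bounds[1:])])
    return VitalsSeries(signal, uniq, med)


def exclude_extremes(series: VitalsSeries) -> VitalsSeries:
    """Drop physiologically impossible values using strict thresholds.

    ICP samples > 100 or < 0 mmHg and MAP samples > 150 or < 20 mmHg are
    removed; values exactly on a boundary are retained.  CPP is derived after
    filtering and must never be passed here.
    """
    if series.signal == "cpp":
        raise PreprocessingError(
            "CPP is derived after filtering ICP and MAP and is never range-filtered"
        )
    lo, hi = EXTREME_LIMITS[series.signal]
    keep = (series.values >= lo) & (series.values <= hi)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("exclude_extremes: dropped %d %s samples outside [%g, %g] mmHg",
                    n_dropped, series.signal, lo, hi)
    return VitalsSeries(series.signal, series.times[keep], series.values[keep])


def derive_cpp(map_series: VitalsSeries, icp_series: VitalsSeries) -> VitalsSeries:
    """Cerebral perfusion pressure, CPP(t) = MAP(t) - ICP(t).

    Computed only at minutes present in *both* filtered inputs; minutes
    missing in either signal are absent from the output (no imputation).
    """
    if map_series.signal != "map" or icp_series.signal != "icp":
        raise PreprocessingError("derive_cpp expects (map_series, icp_series)")
    common, i_map, i_icp = np.intersect1d(
        map_series.times, icp_series.times, return_indices=True
    )
    return VitalsSeries("cpp", common, map_series.values[i_map] - icp_series.values[i_icp])


@dataclass(frozen=True)
class PatientRecord:
    """One monitored patient: demographics, outcome and pressure series.

    ``outcome`` is 30-day all-cause mortality from ICU admission
    (1 = dead within 30 days, 0 = alive).  ``cpp`` is always the minute-wise
    MAP - ICP on the intersection grid of the filtered inputs.
    ``monitoring_end_min`` marks the end of the monitoring span (death,
    discharge or the 120-h horizon, whichever came first).
    """

    patient_id: str
    age_years: float
    outcome: int
    icp: VitalsSeries
    map: VitalsSeries
    cpp: VitalsSeries
    monitoring_end_min: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 (alive) or 1 (dead within 30 days)")
        if self.age_years < 0:
            raise ValueError("age_years must be nonnegative")

    def series(self, signal: str) -> VitalsSeries:
        return {"icp": self.icp, "map": self.map, "cpp": self.cpp}[signal]


@dataclass
class Cohort:
    """A set of patients with unique ids."""

    patients: list[PatientRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def outcomes(self) -> pd.Series:
        return pd.Series(
            {p.patient_id: p.outcome for p in self.patients}, name="outcome", dtype=int
        )


def build_patient(
    patient_id: str,
    age_years: float,
    outcome: int,
    icp_raw: VitalsSeries,
    map_raw: VitalsSeries,
    monitoring_end_min: int | None = None,
) -> PatientRecord:
    """Assemble a preprocessed patient: filter extremes, derive CPP, truncate.

    The input series are on the minute grid already (use
    :func:`round_and_deduplicate` upstream for raw second-stamped data).
    """
    icp = exclude_extremes(icp_raw)
    map_ = exclude_extremes(map_raw)
    cpp = derive_cpp(map_, icp)
    end = monitoring_end_min
    if end is None:
        end = max(icp.span_min, map_.span_min)
    patient = PatientRecord(
        patient_id=str(patient_id),
        age_years=float(age_years),
        outcome=int(outcome),
        icp=icp,
        map=map_,
        cpp=cpp,
        monitoring_end_min=int(end),
    )
    return truncate_to_horizon(patient, HORIZON_H)


def truncate_to_horizon(patient: PatientRecord, horizon_h: float = HORIZON_H) -> PatientRecord:
    """Drop all samples at or beyond ``horizon_h`` (half-open ``[0, horizon)``)."""
    if horizon_h <= 0:
        raise ValueError("horizon_h must be positive")
    cut = horizon_h * 60.0

    def _trunc(s: VitalsSeries) -> VitalsSeries:
        keep = s.times < cut
        return VitalsSeries(s.signal, s.times[keep], s.values[keep])

    return replace(
        patient,
        icp=_trunc(patient.icp),
        map=_trunc(patient.map),
        cpp=_trunc(patient.cpp),
        monitoring_end_min=min(patient.monitoring_end_min, int(cut)),
    )


def is_eligible(
    patient: PatientRecord,
    min_span_h: float = MIN_SPAN_H,
    min_coverage: float = 0.0,
) -> bool:
    """Inclusion rule: adult (>= 16 y) with ICP data spanning >= 24 h.

    "ICP data for at least 24 h" is read as monitoring *span*: the last ICP
    sample falls at or beyond minute 1440.  ``min_coverage`` optionally also
    requires that fraction of minutes within the span to carry an ICP sample
    (default 0: span only).
    """
    if patient.age_years < ADULT_AGE_YEARS:
        return False
    span = patient.icp.span_min
    if span < min_span_h * 60.0:
        return False
    if min_coverage > 0 and span > 0:
        if len(patient.icp) / (span + 1) < min_coverage:
            return False
    return True


# ---------------------------------------------------------------------------
# CSV ingestion (long-format vitals + cohort metadata)
# ---------------------------------------------------------------------------

VITALS_COLUMNS = ["patient_id", "time_min", "signal", "value"]
META_COLUMNS = ["patient_id", "age_years", "outcome"]


def load_cohort(
    vitals_csv,
    metadata_csv,
    label: str = "",
    eligibility: bool = True,
) -> Cohort:
    """Read a cohort from long-format vitals and metadata CSV files.

    The vitals file has columns ``patient_id,time_min,signal,value`` with
    signal in {ICP, MAP}; CPP rows in input files are ignored with a warning
    because CPP is derived.  The metadata file has
    ``patient_id,age_years,outcome[,admission_iso8601]``.  Extreme values are
    excluded, CPP derived, the 120-h horizon applied and (by default) the
    eligibility rule enforced.  Row counts and exclusions are logged.
    """
    vit = pd.read_csv(vitals_csv)
    missing = [c for c in VITALS_COLUMNS if c not in vit.columns]
    if missing:
        raise PreprocessingError(f"vitals file lacks columns {missing}")
    meta = pd.read_csv(metadata_csv)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise PreprocessingError(f"metadata file lacks columns {missing}")

    vit["signal"] = vit["signal"].str.lower()
    n_cpp = int((vit["signal"] == "cpp").sum())
    if n_cpp:
        logger.warning("ignoring %d CPP rows in input vitals (CPP is derived)", n_cpp)
        vit = vit[vit["signal"] != "cpp"]
    bad = ~vit["signal"].isin(["icp", "map"])
    if bad.any():
        raise PreprocessingError(
            f"unknown signal values in vitals file: {sorted(vit.loc[bad, 'signal'].unique())}"
        )
    logger.info("read %d vitals rows for %d patients", len(vit), vit["patient_id"].nunique())

    patients: list[PatientRecord] = []
    n_ineligible = 0
    grouped = vit.groupby("patient_id", sort=True)
    for _, row in meta.sort_values("patient_id").iterrows():
        pid = row["patient_id"]
        try:
            g = grouped.get_group(pid)
        except KeyError:
            logger.warning("patient %s has metadata but no vitals; skipped", pid)
            continue
        series = {}
        for sig in ("icp", "map"):
            sg = g[g["signal"] == sig].sort_values("time_min")
            t = sg["time_min"].to_numpy(dtype=np.int64)
            if np.any(np.diff(t) == 0):
                raise PreprocessingError(
                    f"patient {pid}: duplicate {sig} samples on one minute "
                    "(pre-aggregate with round_and_deduplicate)"
                )
            series[sig] = VitalsSeries(sig, t, sg["value"].to_numpy(dtype=np.float64))
        patient = build_patient(
            pid, row["age_years"], row["outcome"], series["icp"], series["map"]
        )
        if eligibility and not is_eligible(patient):
            n_ineligible += 1
            continue
        patients.append(patient)
    if n_ineligible:
        logger.info("excluded %d ineligible patients (age < 16 or ICP span < 24 h)",
                    n_ineligible)
    return Cohort(patients, label=label)


def cohort_to_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format vitals and metadata frames (ICP and MAP only; CPP derived)."""
    chunks = []
    for p in cohort:
        for sig in ("icp", "map"):
            s = p.series(sig)
            chunks.append(pd.DataFrame({
                "patient_id": p.patient_id,
                "time_min": s.times,
                "signal": sig,
                "value": s.values,
            }))
    vitals = (pd.concat(chunks, ignore_index=True) if chunks
              else pd.DataFrame(columns=VITALS_COLUMNS))
    meta = pd.DataFrame({
        "patient_id": [p.patient_id for p in cohort],
        "age_years": [p.age_years for p in cohort],
        "outcome": [p.outcome for p in cohort],
    })
    return vitals, meta
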