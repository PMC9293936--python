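"""Rolling-time-window feature engineering for ICP/MAP/CPP series.

At each prediction time ``t_h`` (every 8 h from 24 h to 120 h after
admission) a candidate feature vector is evaluated from three window
geometries, all half-open in minutes:

* ``begin`` -- the statistic over the first 24-h window ``[0, 1440)``;
* ``end``   -- the statistic over the trailing 8-h window ``[t-8h, t)``;
* ``coef``  -- the OLS slope of the statistic's sequence over rolling 4-h
  windows (1-h stride, windows ending at whole hours 4, 5, ..., t) regressed
  on window end time, i.e. the trend of the statistic in stat-units per hour
  from the start of monitoring up to the prediction time.

Window statistics: ``avg`` (plain mean), ``min``, ``max``, ``diff`` (mean of
signed consecutive differences), ``var`` (population variance), ``q90`` /
``q10`` (percentiles, linear interpolation), and the threshold fractions
``ht20`` / ``lt10`` (share of ICP samples strictly above 20 / below 10 mmHg)
and ``ht120`` (share of MAP samples strictly above 120 mmHg).  Statistics are
computed over whatever samples fall in the window -- gaps are simply absent.
An empty window makes the feature missing, and the patient is then excluded
from that prediction time-point downstream.

The default grammar enumerates
``{icp, map, cpp} x {avg, diff, var, q90, q10} x {begin, end, coef}`` plus
the three threshold statistics with all aggregations: 54 signal features,
plus age in decade bins (``agec``), 55 candidates in total.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .vitals import Cohort, PatientRecord, VitalsSeries, is_eligible

#: prediction schedule (hours): every 8 h from 24 h to 120 h
SCHEDULE_H: tuple[int, ...] = tuple(range(24, 121, 8))

_THRESHOLD_STATS = {"ht20": "icp", "lt10": "icp", "ht120": "map"}
_MINMAX_STATS = ("min", "max")


class FeatureError(ValueError):
    pass


def _validate_pairing(signal: str, kind: str) -> None:
    owner = _THRESHOLD_STATS.get(kind)
    if owner is not None and signal != owner:
        raise FeatureError(f"window statistic {kind!r} is only valid for {owner.upper()}")


def window_stat(
    series: VitalsSeries,
    a_min: float,
    b_min: float,
    kind: str,
    *,
    signed_diff: bool = True,
) -> float:
    """One window statistic over samples in ``[a_min, b_min)``.

    Returns NaN for an empty window; ``diff`` and ``var`` additionally
    require at least two samples.  ``diff`` is the mean of consecutive
    differences of the in-window values ordered by time (signed by default;
    absolute differences behind the ``signed_diff`` flag since the sign
    convention is a modelling choice).  ``var`` is the population (1/n)
    variance; percentiles interpolate linearly between order statistics.
    """
    if a_min >= b_min:
        raise FeatureError("window must satisfy a < b")
    _validate_pairing(series.signal, kind)
    v = series.slice_window(a_min, b_min)
    n = v.size
    if n == 0:
        return math.nan
    if kind == "avg":
        return float(v.mean())
    if kind == "min":
        return float(v.min())
    if kind == "max":
        return float(v.max())
    if kind == "diff":
        if n < 2:
            return math.nan
        d = np.diff(v)
        return float(d.mean() if signed_diff else np.abs(d).mean())
    if kind == "var":
        if n < 2:
            return math.nan
        return float(v.var())  # population variance
    if kind == "q90":
        return float(np.percentile(v, 90))
    if kind == "q10":
        return float(np.percentile(v, 10))
    if kind == "ht20":
        return float((v > 20.0).mean())
    if kind == "lt10":
        return float((v < 10.0).mean())
    if kind == "ht120":
        return float((v > 120.0).mean())
    raise FeatureError(f"unknown window statistic {kind!r}")


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form simple-OLS slope sum((x-xb)(y-yb)) / sum((x-xb)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return math.nan
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return math.nan
    return float(xc @ (y - y.mean()) / denom)


def begin_feature(series: VitalsSeries, kind: str, *, begin_window_h: float = 24.0,
                  signed_diff: bool = True) -> float:
    """Statistic over the first 24-h window ``[0, 1440)`` minutes."""
    return window_stat(series, 0.0, begin_window_h * 60.0, kind, signed_diff=signed_diff)


def end_feature(series: VitalsSeries, kind: str, t_h: float, *,
                end_window_h: float = 8.0, signed_diff: bool = True) -> float:
    """Statistic over the trailing window ``[t-8h, t)``."""
    if t_h < 24:
        raise FeatureError("predictions start at 24 h")
    return window_stat(series, (t_h - end_window_h) * 60.0, t_h * 60.0, kind,
                       signed_diff=signed_diff)


def rolling_stat_sequence(
    series: VitalsSeries,
    kind: str,
    t_h: float,
    *,
    window_h: float = 4.0,
    stride_h: float = 1.0,
    signed_diff: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Window end-times (hours) and statistic values for rolling windows.

    Windows are ``[k - window_h, k)`` hours for ``k = window_h, window_h +
    stride_h, ..., t_h``.  Missing (empty-window) entries are NaN.
    """
    ends = np.arange(window_h, t_h + 1e-9, stride_h)
    vals = np.array([
        window_stat(series, (k - window_h) * 60.0, k * 60.0, kind, signed_diff=signed_diff)
        for k in ends
    ])
    return ends, vals


def coef_feature(series: VitalsSeries, kind: str, t_h: float, *,
                 window_h: float = 4.0, stride_h: float = 1.0,
                 signed_diff: bool = True) -> float:
    """Trend (OLS slope per hour) of the rolling-window statistic up to ``t_h``.

    Missing window values are dropped before the regression; fewer than two
    non-missing windows make the trend itself missing.
    """
    if t_h < 24:
        raise FeatureError("predictions start at 24 h")
    ends, vals = rolling_stat_sequence(series, kind, t_h, window_h=window_h,
                                       stride_h=stride_h, signed_diff=signed_diff)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        return math.nan
    return ols_slope(ends[ok], vals[ok])


def age_decile(age_years: float) -> int:
    """Age in decade bins: floor(age/10) clipped to [1, 9]."""
    if age_years < 0:
        raise FeatureError("age must be nonnegative")
    return int(min(max(math.floor(age_years / 10.0), 1), 9))


@dataclass(frozen=True)
class FeatureGrammar:
    """The candidate-feature grammar and its window geometry.

    The default enumerates the 54 signal features plus ``agec``.  ``min`` and
    ``max`` window statistics are implemented and can be switched on
    (``include_min_max``), growing the candidate set to 73.
    """

    signals: tuple[str, ...] = ("icp", "map", "cpp")
    base_stats: tuple[str, ...] = ("avg", "diff", "var", "q90", "q10")
    aggregations: tuple[str, ...] = ("begin", "end", "coef")
    include_min_max: bool = False
    include_age: bool = True
    signed_diff: bool = True
    begin_window_h: float = 24.0
    end_window_h: float = 8.0
    rolling_window_h: float = 4.0
    stride_h: float = 1.0

    def stats_for(self, signal: str) -> tuple[str, ...]:
        stats = self.base_stats
        if self.include_min_max:
            stats = stats + _MINMAX_STATS
        extra = tuple(k for k, owner in _THRESHOLD_STATS.items() if owner == signal)
        return stats + extra

    def feature_names(self) -> list[str]:
        """Deterministic enumeration: signal, then statistic, then aggregation.

        The plain mean ('avg') renders without the stat token (``icp_end``,
        ``icp_coef``); others as ``<signal>_<stat>_<agg>`` (``cpp_diff_coef``).
        """
        names: list[str] = []
        for sig in self.signals:
            for stat in self.stats_for(sig):
                for agg in self.aggregations:
                    if stat == "avg":
                        names.append(f"{sig}_{agg}")
                    else:
                        names.append(f"{sig}_{stat}_{agg}")
        if self.include_age:
            names.append("agec")
        return names

    def parse(self, name: str) -> tuple[str, str, str]:
        """Split a rendered feature name into (signal, stat, aggregation)."""
        if name == "agec":
            return ("agec", "", "")
        parts = name.split("_")
        if len(parts) == 2:
            return (parts[0], "avg", parts[1])
        if len(parts) == 3:
            return (parts[0], parts[1], parts[2])
        raise FeatureError(f"unparseable feature name {name!r}")

    def digest(self) -> str:
        """Stable hash of the grammar, embedded in model artifacts."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def enumerate_candidate_features(grammar: FeatureGrammar | None = None) -> list[str]:
    """Ordered candidate feature names for a grammar (default: the 55)."""
    return (grammar or FeatureGrammar()).feature_names()


def featurize(patient: PatientRecord, t_h: float,
              grammar: FeatureGrammar | None = None) -> dict[str, float]:
    """Evaluate every candidate feature for one patient at one scheduled time.

    ``t_h`` must lie on the 8-h prediction schedule starting at 24 h.
    Features whose window holds no samples are NaN; downstream, any missing
    required feature excludes the patient from that time-point's estimate.
    """
    grammar = grammar or FeatureGrammar()
    if t_h not in SCHEDULE_H:
        raise FeatureError(f"t_h={t_h} is off the 8-h prediction schedule {SCHEDULE_H}")
    if not is_eligible(patient):
        raise FeatureError(f"patient {patient.patient_id} is not eligible")
    out: dict[str, float] = {}
    for name in grammar.feature_names():
        sig, stat, agg = grammar.parse(name)
        if sig == "agec":
            out[name] = float(age_decile(patient.age_years))
            continue
        series = patient.series(sig)
        kw = dict(signed_diff=grammar.signed_diff)
        if agg == "begin":
            out[name] = begin_feature(series, stat,
                                      begin_window_h=grammar.begin_window_h, **kw)
        elif agg == "end":
            out[name] = end_feature(series, stat, t_h,
                                    end_window_h=grammar.end_window_h, **kw)
        elif agg == "coef":
            out[name] = coef_feature(series, stat, t_h,
                                     window_h=grammar.rolling_window_h,
                                     stride_h=grammar.stride_h, **kw)
        else:  # pragma: no cover - grammar enumeration guards this
            raise FeatureError(f"unknown aggregation {agg!r}")
    return out


def _patient_feature_rows(patient: PatientRecord, grammar: FeatureGrammar,
                          schedule: tuple[int, ...]) -> list[dict]:
    """All scheduled feature vectors for one patient, sharing rolling stats.

    The per-4-h-window statistic sequences are computed once up to the last
    scheduled time and reused for every prediction's trend slope, which keeps
    cohort featurization linear in monitoring length.
    """
    times = [t for t in schedule if t * 60 <= patient.monitoring_end_min]
    if not times:
        return []
    t_max = times[-1]
    names = grammar.feature_names()
    parsed = [grammar.parse(n) for n in names]

    # rolling sequences per (signal, stat) used by any coef feature
    rolling: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    begin_vals: dict[tuple[str, str], float] = {}
    for (sig, stat, agg), name in zip(parsed, names):
        if sig == "agec":
            continue
        key = (sig, stat)
        series = patient.series(sig)
        if agg == "coef" and key not in rolling:
            rolling[key] = rolling_stat_sequence(
                series, stat, t_max, window_h=grammar.rolling_window_h,
                stride_h=grammar.stride_h, signed_diff=grammar.signed_diff)
        if agg == "begin" and key not in begin_vals:
            begin_vals[key] = begin_feature(series, stat,
                                            begin_window_h=grammar.begin_window_h,
                                            signed_diff=grammar.signed_diff)

    rows = []
    agec = float(age_decile(patient.age_years))
    for t in times:
        row: dict[str, float] = {"patient_id": patient.patient_id, "t_h": t,
                                 "outcome": patient.outcome}
        for (sig, stat, agg), name in zip(parsed, names):
            if sig == "agec":
                row[name] = agec
            elif agg == "begin":
                row[name] = begin_vals[(sig, stat)]
            elif agg == "end":
                row[name] = end_feature(patient.series(sig), stat, t,
                                        end_window_h=grammar.end_window_h,
                                        signed_diff=grammar.signed_diff)
            else:
                ends, vals = rolling[(sig, stat)]
                m = ends <= t + 1e-9
                ok = m & ~np.isnan(vals)
                row[name] = (ols_slope(ends[ok], vals[ok])
                             if ok.sum() >= 2 else math.nan)
        rows.append(row)
    return rows


def featurize_cohort(cohort: Cohort, grammar: FeatureGrammar | None = None,
                     schedule: tuple[int, ...] = SCHEDULE_H) -> pd.DataFrame:
    """Wide feature table: one row per (patient, prediction time).

    Columns: ``patient_id``, ``t_h``, ``outcome`` then the candidate feature
    names in grammar order; missing features are NaN.  A patient contributes
    rows only at scheduled times up to the end of their monitoring.
    """
    grammar = grammar or FeatureGrammar()
    rows: list[dict] = []
    for patient in cohort:
        if not is_eligible(patient):
            continue
        rows.extend(_patient_feature_rows(patient, grammar, tuple(schedule)))
    columns = ["patient_id", "t_h", "outcome"] + grammar.feature_names()
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)
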