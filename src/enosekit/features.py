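"""Per-sensor descriptor extraction for segmented e-nose traces.

Each preprocessed sensor trace is summarised by 33 named descriptors in five
families:

* **basic statistics** (9): max, min, amplitude (max - min), mean, median,
  standard deviation, interquartile range, excess kurtosis, skewness;
* **time-related** (8, seconds): 10%->90% rise time, 90%->10% fall time,
  time over mean, time over median, time over 90% of max, time from start to
  maximum, time of maximum slope, time of minimum slope;
* **area-related** (5, units x seconds): total area under the curve, area
  from start to the maximum, area over the mean, area over the median, area
  over 90% of max;
* **ratios** (5): AUC/amplitude and each "area over X" divided by the
  matching "time over X";
* **slope statistics** (6, units/second): max, min, mean, median, SD and IQR
  of the first-difference slopes.

Conventions pinned here (the descriptor names alone do not fix them): SD and
IQR are population-form (ddof=0, linear-interpolation quantiles); kurtosis is
Fisher excess and skewness the Fisher-Pearson moment coefficient, both 0 for
a constant trace; threshold crossings are located by linear interpolation
between samples (first upward crossings for the rise, last downward for the
fall); "over X" durations count strict exceedances times dt; areas use the
trapezoidal rule on the clipped signal; slopes are timestamped at interval
midpoints with ties broken by earliest time; a ratio with zero denominator
is 0, keeping the feature matrix complete.  The 10%/90% thresholds are
fractions of the maximum of the *baseline-anchored* segment (signal minus its
first value), so they remain meaningful under a baseline offset.

A full sample is 28 sensors x 33 descriptors = 924 features, named
``<sensor_id>__<feature>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .signals import BreathSample, QCError, SensorTrace

logger = logging.getLogger(__name__)

BASIC_FEATURES = (
    "max", "min", "amplitude", "mean", "median", "std", "iqr",
    "kurtosis", "skewness",
)
TIME_FEATURES = (
    "rise_time_10_90", "fall_time_90_10", "time_over_mean",
    "time_over_median", "time_over_90", "time_to_max",
    "time_of_max_slope", "time_of_min_slope",
)
AREA_FEATURES = (
    "auc_total", "auc_start_to_max", "area_over_mean",
    "area_over_median", "area_over_90",
)
RATIO_FEATURES = (
    "auc_to_amplitude", "area90_to_time90", "area_mean_to_time_mean",
    "area_median_to_time_median", "area_start_max_to_time_start_max",
)
SLOPE_FEATURES = (
    "slope_max", "slope_min", "slope_mean", "slope_median",
    "slope_std", "slope_iqr",
)

#: canonical per-sensor descriptor order; column order in every FeatureMatrix.
FEATURE_NAMES: tuple[str, ...] = (
    BASIC_FEATURES + TIME_FEATURES + AREA_FEATURES + RATIO_FEATURES
    + SLOPE_FEATURES
)

N_FEATURES_PER_SENSOR = len(FEATURE_NAMES)  # 33
MIN_TRACE_LENGTH = 4


class FeatureError(ValueError):
    """Trace unsuitable for descriptor extraction."""


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0.0:
        logger.warning("ratio %s has zero denominator; set to 0", name)
        return 0.0
    return num / den


def basic_stats_features(trace: SensorTrace) -> dict[str, float]:
    """The nine distributional descriptors of a segmented trace."""
    v = trace.values
    if v.size < MIN_TRACE_LENGTH:
        raise FeatureError(
            f"trace must have at least {MIN_TRACE_LENGTH} samples for kurtosis"
        )
    sd = float(np.std(v))
    if sd == 0.0:
        kurt, skew = 0.0, 0.0
    else:
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
        skew = float(stats.skew(v, bias=True))
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    return {
        "max": float(np.max(v)),
        "min": float(np.min(v)),
        "amplitude": float(np.max(v) - np.min(v)),
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "std": sd,
        "iqr": float(q3 - q1),
        "kurtosis": kurt,
        "skewness": skew,
    }


def _first_upward_crossing(y: np.ndarray, level: float, dt: float) -> Optional[float]:
    """Time of the first upward crossing of ``level``, linear interpolation."""
    if y[0] >= level:
        return 0.0
    below = y[:-1] < level
    above = y[1:] >= level
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return (i + frac) * dt


def _last_downward_crossing(y: np.ndarray, level: float, dt: float) -> Optional[float]:
    """Time of the last downward crossing of ``level``, linear interpolation."""
    above = y[:-1] >= level
    below = y[1:] < level
    idx = np.flatnonzero(above & below)
    if idx.size == 0:
        return None
    i = int(idx[-1])
    frac = (y[i] - level) / (y[i] - y[i + 1])
    return (i + frac) * dt


def time_features(trace: SensorTrace) -> dict[str, float]:
    """The eight time-related descriptors, in seconds.

    Thresholds are fractions of the maximum of the baseline-anchored segment
    ``y = S - S[0]``.  A threshold that is never crossed yields 0 for the
    corresponding feature (degenerate trace).
    """
    v = trace.values
    dt = trace.dt_s
    y = v - v[0]
    m = float(np.max(y))

    rise = fall = time_over_90 = 0.0
    if m > 0:
        t10_up = _first_upward_crossing(y, 0.1 * m, dt)
        t90_up = _first_upward_crossing(y, 0.9 * m, dt)
        if t10_up is not None and t90_up is not None:
            rise = max(t90_up - t10_up, 0.0)
        t90_dn = _last_downward_crossing(y, 0.9 * m, dt)
        t10_dn = _last_downward_crossing(y, 0.1 * m, dt)
        if t90_dn is not None and t10_dn is not None:
            fall = max(t10_dn - t90_dn, 0.0)
        time_over_90 = dt * int(np.count_nonzero(y > 0.9 * m))
    else:
        logger.debug("trace %s: non-positive anchored max; threshold "
                     "features set to 0", trace.sensor_id)

    mean, median = float(np.mean(v)), float(np.median(v))
    slopes = np.diff(v) / dt
    if slopes.size == 0:
        t_max_slope = t_min_slope = 0.0
    else:
        t_max_slope = (int(np.argmax(slopes)) + 0.5) * dt
        t_min_slope = (int(np.argmin(slopes)) + 0.5) * dt
    return {
        "rise_time_10_90": rise,
        "fall_time_90_10": fall,
        "time_over_mean": dt * int(np.count_nonzero(v > mean)),
        "time_over_median": dt * int(np.count_nonzero(v > median)),
        "time_over_90": time_over_90,
        "time_to_max": float(int(np.argmax(v)) * dt),
        "time_of_max_slope": t_max_slope,
        "time_of_min_slope": t_min_slope,
    }


def area_features(trace: SensorTrace) -> dict[str, float]:
    """The five trapezoidal-area descriptors (units x seconds)."""
    v = trace.values
    if v.size < 2:
        raise FeatureError("trace must have at least 2 samples for areas")
    dt = trace.dt_s
    y = v - v[0]
    m = float(np.max(y))
    i_max = int(np.argmax(v))

    def over(level_values: np.ndarray) -> float:
        return float(np.trapezoid(np.clip(level_values, 0.0, None), dx=dt))

    auc_start_max = (
        float(np.trapezoid(v[: i_max + 1], dx=dt)) if i_max >= 1 else 0.0
    )
    return {
        "auc_total": float(np.trapezoid(v, dx=dt)),
        "auc_start_to_max": auc_start_max,
        "area_over_mean": over(v - np.mean(v)),
        "area_over_median": over(v - np.median(v)),
        "area_over_90": over(y - 0.9 * m) if m > 0 else 0.0,
    }


def ratio_features(trace: SensorTrace) -> dict[str, float]:
    """Area-to-duration ratios; zero denominators resolve to 0."""
    b = basic_stats_features(trace)
    t = time_features(trace)
    a = area_features(trace)
    return {
        "auc_to_amplitude": _safe_ratio(a["auc_total"], b["amplitude"],
                                        "auc_to_amplitude"),
        "area90_to_time90": _safe_ratio(a["area_over_90"], t["time_over_90"],
                                        "area90_to_time90"),
        "area_mean_to_time_mean": _safe_ratio(
            a["area_over_mean"], t["time_over_mean"], "area_mean_to_time_mean"),
        "area_median_to_time_median": _safe_ratio(
            a["area_over_median"], t["time_over_median"],
            "area_median_to_time_median"),
        "area_start_max_to_time_start_max": _safe_ratio(
            a["auc_start_to_max"], t["time_to_max"],
            "area_start_max_to_time_start_max"),
    }


def slope_features(trace: SensorTrace) -> dict[str, float]:
    """Distributional statistics of the first-difference slope sequence."""
    v = trace.values
    if v.size < 2:
        raise FeatureError("trace must have at least 2 samples for slopes")
    slopes = np.diff(v) / trace.dt_s
    q1, q3 = np.percentile(slopes, [25, 75])
    return {
        "slope_max": float(np.max(slopes)),
        "slope_min": float(np.min(slopes)),
        "slope_mean": float(np.mean(slopes)),
        "slope_median": float(np.median(slopes)),
        "slope_std": float(np.std(slopes)),
        "slope_iqr": float(q3 - q1),
    }


def extract_trace_features(trace: SensorTrace) -> dict[str, float]:
    """All 33 descriptors of one trace, in canonical order."""
    out: dict[str, float] = {}
    out.update(basic_stats_features(trace))
    out.update(time_features(trace))
    out.update(area_features(trace))
    out.update(ratio_features(trace))
    out.update(slope_features(trace))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_sample_features(sample: BreathSample) -> dict[str, float]:
    """Concatenate the per-sensor descriptors of a QC-passed sample.

    Sensors are ordered by sensor_id; the result has exactly
    28 x 33 = 924 entries named ``<sensor_id>__<feature>``.
    """
    if sample.qc_state != "pass":
        raise QCError(
            f"sample {sample.sample_id} has qc_state={sample.qc_state!r}; "
            "only QC-passed samples are featurized"
        )
    values: dict[str, float] = {}
    for sid in sample.sensor_ids:
        feats = extract_trace_features(sample.trace(sid))
        for name, val in feats.items():
            values[f"{sid}__{name}"] = val
    return values


@dataclass
class FeatureMatrix:
    """Samples x named features with class labels.

    ``frame`` is indexed by sample_id with one column per feature in a fixed
    canonical order; ``labels`` shares the index (0 healthy, 1 sick, -1
    unknown).
    """

    frame: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.frame.index.equals(self.labels.index):
            raise ValueError("frame and labels must share the sample index")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def X(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        labels = df.pop("label").astype(int)
        return cls(frame=df, labels=labels)


def build_feature_matrix(samples) -> FeatureMatrix:
    """Featurize a list of processed, QC-passed samples."""
    rows, labels, ids = [], [], []
    for s in samples:
        rows.append(extract_sample_features(s))
        labels.append(-1 if s.label is None else int(s.label))
        ids.append(s.sample_id)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    return FeatureMatrix(frame=frame, labels=pd.Series(labels, index=frame.index,
                                                       name="label"))
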