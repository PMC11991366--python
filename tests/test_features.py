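"""Descriptor extraction: hand oracles, brute-force equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enosekit.features import (
    AREA_FEATURES,
    BASIC_FEATURES,
    FEATURE_NAMES,
    RATIO_FEATURES,
    SLOPE_FEATURES,
    TIME_FEATURES,
    FeatureError,
    area_features,
    basic_stats_features,
    extract_trace_features,
    ratio_features,
    slope_features,
    time_features,
)
from enosekit.signals import SensorTrace

# ---------------------------------------------------------------------------
# independent brute-force oracle: direct formula recomputation, plain Python
# ---------------------------------------------------------------------------


def _quantile(sorted_vals, q):
    """Linear-interpolation quantile on a pre-sorted list."""
    n = len(sorted_vals)
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def _trapz(vals, dt):
    return sum((vals[i] + vals[i + 1]) / 2.0 * dt for i in range(len(vals) - 1))


def _first_up(y, level, dt):
    if y[0] >= level:
        return 0.0
    for i in range(len(y) - 1):
        if y[i] < level <= y[i + 1]:
            return (i + (level - y[i]) / (y[i + 1] - y[i])) * dt
    return None


def _last_down(y, level, dt):
    out = None
    for i in range(len(y) - 1):
        if y[i] >= level > y[i + 1]:
            out = (i + (y[i] - level) / (y[i] - y[i + 1])) * dt
    return out


def oracle_features(values, dt):
    """Recompute all 33 descriptors from their definitions."""
    v = [float(x) for x in values]
    n = len(v)
    mx, mn = max(v), min(v)
    mean = sum(v) / n
    sv = sorted(v)
    median = _quantile(sv, 0.5)
    var = sum((x - mean) ** 2 for x in v) / n
    sd = var ** 0.5
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = sum((x - mean) ** 3 for x in v) / n / sd**3
        kurt = sum((x - mean) ** 4 for x in v) / n / sd**4 - 3.0
    out = {
        "max": mx, "min": mn, "amplitude": mx - mn, "mean": mean,
        "median": median, "std": sd,
        "iqr": _quantile(sv, 0.75) - _quantile(sv, 0.25),
        "kurtosis": kurt, "skewness": skew,
    }

    y = [x - v[0] for x in v]
    m = max(y)
    rise = fall = t_over_90 = 0.0
    if m > 0:
        t10u, t90u = _first_up(y, 0.1 * m, dt), _first_up(y, 0.9 * m, dt)
        if t10u is not None and t90u is not None:
            rise = max(t90u - t10u, 0.0)
        t90d, t10d = _last_down(y, 0.9 * m, dt), _last_down(y, 0.1 * m, dt)
        if t90d is not None and t10d is not None:
            fall = max(t10d - t90d, 0.0)
        t_over_90 = dt * sum(1 for x in y if x > 0.9 * m)
    slopes = [(v[i + 1] - v[i]) / dt for i in range(n - 1)]
    i_max = v.index(mx)
    out.update({
        "rise_time_10_90": rise, "fall_time_90_10": fall,
        "time_over_mean": dt * sum(1 for x in v if x > mean),
        "time_over_median": dt * sum(1 for x in v if x > median),
        "time_over_90": t_over_90,
        "time_to_max": i_max * dt,
        "time_of_max_slope": (slopes.index(max(slopes)) + 0.5) * dt,
        "time_of_min_slope": (slopes.index(min(slopes)) + 0.5) * dt,
    })

    out.update({
        "auc_total": _trapz(v, dt),
        "auc_start_to_max": _trapz(v[: i_max + 1], dt) if i_max >= 1 else 0.0,
        "area_over_mean": _trapz([max(x - mean, 0.0) for x in v], dt),
        "area_over_median": _trapz([max(x - median, 0.0) for x in v], dt),
        "area_over_90": _trapz([max(x - 0.9 * m, 0.0) for x in y], dt)
        if m > 0 else 0.0,
    })

    def ratio(a, b):
        return a / b if b != 0 else 0.0

    out.update({
        "auc_to_amplitude": ratio(out["auc_total"], out["amplitude"]),
        "area90_to_time90": ratio(out["area_over_90"], out["time_over_90"]),
        "area_mean_to_time_mean": ratio(out["area_over_mean"],
                                        out["time_over_mean"]),
        "area_median_to_time_median": ratio(out["area_over_median"],
                                            out["time_over_median"]),
        "area_start_max_to_time_start_max": ratio(out["auc_start_to_max"],
                                                  out["time_to_max"]),
    })

    ss = sorted(slopes)
    smean = sum(slopes) / len(slopes)
    svar = sum((x - smean) ** 2 for x in slopes) / len(slopes)
    out.update({
        "slope_max": max(slopes), "slope_min": min(slopes),
        "slope_mean": smean, "slope_median": _quantile(ss, 0.5),
        "slope_std": svar ** 0.5,
        "slope_iqr": _quantile(ss, 0.75) - _quantile(ss, 0.25),
    })
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def test_family_cardinalities():
    assert (len(BASIC_FEATURES), len(TIME_FEATURES), len(AREA_FEATURES),
            len(RATIO_FEATURES), len(SLOPE_FEATURES)) == (9, 8, 5, 5, 6)
    assert len(FEATURE_NAMES) == 33
    assert len(set(FEATURE_NAMES)) == 33


def test_hand_oracle_tent_trace(tent_trace):
    """[0,1,2,1,0] at dt=1: every worked hand value."""
    f = extract_trace_features(tent_trace)
    assert f["max"] == 2.0
    assert f["min"] == 0.0
    assert f["amplitude"] == 2.0
    assert f["mean"] == pytest.approx(0.8)
    assert f["median"] == 1.0
    assert f["rise_time_10_90"] == pytest.approx(1.6)
    assert f["fall_time_90_10"] == pytest.approx(1.6)
    assert f["time_to_max"] == 2.0
    assert f["time_of_max_slope"] == 0.5
    assert f["time_of_min_slope"] == 2.5
    assert f["auc_total"] == pytest.approx(4.0)
    assert f["auc_start_to_max"] == pytest.approx(2.0)
    assert f["auc_to_amplitude"] == pytest.approx(2.0)
    assert f["area_start_max_to_time_start_max"] == pytest.approx(1.0)
    assert f["slope_max"] == 1.0
    assert f["slope_min"] == -1.0
    assert f["slope_mean"] == 0.0
    assert f["slope_median"] == 0.0


def test_constant_trace_degenerates():
    tr = SensorTrace("S01", 1.0, np.full(10, 3.3))
    f = extract_trace_features(tr)
    assert f["amplitude"] == 0.0
    assert f["std"] == 0.0
    assert f["iqr"] == 0.0
    assert f["kurtosis"] == 0.0
    assert f["skewness"] == 0.0
    # thresholds never crossed and zero denominators resolve to 0
    for name in ("rise_time_10_90", "fall_time_90_10", "time_over_90",
                 "area_over_mean") + RATIO_FEATURES:
        assert f[name] == 0.0


def test_symmetric_value_distribution_zero_skewness():
    """A trace whose values are symmetric about their mean has zero skew."""
    tr = SensorTrace("S01", 0.5, np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    f = basic_stats_features(tr)
    assert abs(f["skewness"]) < 1e-12


def test_monotone_trace_has_zero_fall_time():
    tr = SensorTrace("S01", 1.0, np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    assert time_features(tr)["fall_time_90_10"] == 0.0


def test_linear_trace_slope_stats():
    m = 0.7
    tr = SensorTrace("S01", 1.0, m * np.arange(20, dtype=float))
    f = slope_features(tr)
    for name in ("slope_max", "slope_min", "slope_mean", "slope_median"):
        assert f[name] == pytest.approx(m)
    assert f["slope_std"] == pytest.approx(0.0, abs=1e-12)
    assert f["slope_iqr"] == pytest.approx(0.0, abs=1e-12)


def test_reversal_negates_mean_slope():
    rng = np.random.default_rng(3)
    v = rng.normal(size=30)
    fwd = slope_features(SensorTrace("S01", 1.0, v))["slope_mean"]
    rev = slope_features(SensorTrace("S01", 1.0, v[::-1]))["slope_mean"]
    assert fwd == pytest.approx(-rev)


def test_too_short_trace_rejected():
    with pytest.raises(FeatureError, match="at least 4"):
        basic_stats_features(SensorTrace("S01", 1.0, np.array([1.0, 2.0])))


def test_brute_force_oracle_equivalence():
    """All 33 descriptors match independent recomputation on 100 random traces."""
    rng = np.random.default_rng(2210)
    for i in range(100):
        n = int(rng.integers(5, 40))
        dt = float(rng.choice([0.5, 1.0, 2.0]))
        v = rng.normal(1.0, 1.0, n)
        got = extract_trace_features(SensorTrace("S01", dt, v))
        want = oracle_features(v, dt)
        assert set(got) == set(want)
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-9), (
                f"trace {i}, feature {name}"
            )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 50.0),
    seed=st.integers(0, 10_000),
)
def test_amplitude_equivariance(scale, seed):
    """Scaling by c > 0: value-scale features scale by c, time features and
    shape statistics are unchanged."""
    rng = np.random.default_rng(seed)
    v = rng.normal(1.0, 1.0, 25)
    base = extract_trace_features(SensorTrace("S01", 1.0, v))
    scaled = extract_trace_features(SensorTrace("S01", 1.0, scale * v))
    for name in ("max", "min", "amplitude", "mean", "median", "std", "iqr",
                 "slope_max", "slope_min", "slope_mean", "slope_median",
                 "slope_std", "slope_iqr") + AREA_FEATURES:
        assert scaled[name] == pytest.approx(scale * base[name], rel=1e-9,
                                             abs=1e-12), name
    for name in TIME_FEATURES + ("kurtosis", "skewness"):
        assert scaled[name] == pytest.approx(base[name], rel=1e-9,
                                             abs=1e-9), name


def test_ratio_consistency(tent_trace):
    f = ratio_features(tent_trace)
    a = area_features(tent_trace)
    t = time_features(tent_trace)
    assert f["area_mean_to_time_mean"] == pytest.approx(
        a["area_over_mean"] / t["time_over_mean"]
    )
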