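"""File formats and pipeline configuration.

Text formats only: wide per-sample trace CSV (``time_s, S01..S28``), cohort
manifest CSV, feature-matrix CSV, SelectionState JSON, CVReport JSON and
PipelineConfig JSON/YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ConfusionCounts, CVReport, METRIC_NAMES, MetricSet, ModelConfig
from .signals import BreathSample, N_ACTIVE_SENSORS, SensorTrace

#: default humidity-sensitive channels excluded from analysis (the array has
#: 32 sensors of which 4 respond to humidity; which 4 is instrument-specific
#: and therefore configurable).
DEFAULT_HUMIDITY_SENSORS = ("S29", "S30", "S31", "S32")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class PipelineConfig:
    """All tunable pipeline settings, validated on load.

    Defaults reproduce the reference analysis settings: 25 s baseline,
    3-sample smoothing, 3-SD QC rule, 3% top-fraction selection, 100 MC-CV
    iterations with a 20% stratified holdout.
    """

    dt_s: float = 1.0
    baseline_s: float = 25.0
    diff_window: int = 5
    k_thresh: float = 3.0
    min_run: int = 5
    smooth_window: int = 3
    variance_eps: float = 1e-12
    top_fraction: float = 0.03
    model: ModelConfig = field(default_factory=ModelConfig)
    n_iter: int = 100
    holdout: float = 0.2
    seed: int = 0
    humidity_sensor_ids: tuple[str, ...] = DEFAULT_HUMIDITY_SENSORS

    def __post_init__(self) -> None:
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        self.humidity_sensor_ids = tuple(self.humidity_sensor_ids)
        if self.dt_s <= 0 or self.baseline_s <= 0:
            raise FormatError("dt_s and baseline_s must be positive")
        if self.smooth_window % 2 == 0 or self.smooth_window < 1:
            raise FormatError("smooth_window must be odd and >= 1")
        if not 0 < self.top_fraction <= 1:
            raise FormatError("top_fraction must lie in (0, 1]")
        if not 0 < self.holdout < 1:
            raise FormatError("holdout must lie in (0, 1)")
        if self.n_iter < 1:
            raise FormatError("n_iter must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["humidity_sensor_ids"] = list(self.humidity_sensor_ids)
        return d

    def save(self, path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = yaml.safe_load(raw) if path.suffix in (".yml", ".yaml") else json.loads(raw)
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_trace_csv(sample: BreathSample, path) -> None:
    """Wide CSV: ``time_s`` plus one column per sensor, sorted by sensor id."""
    ids = sample.sensor_ids
    first = sample.trace(ids[0])
    data = {"time_s": first.times}
    for sid in ids:
        tr = sample.trace(sid)
        if len(tr) != len(first):
            raise FormatError("traces of one sample must share a length")
        data[sid] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace_csv(
    path,
    humidity_sensor_ids: Sequence[str] = DEFAULT_HUMIDITY_SENSORS,
    sample_id: Optional[str] = None,
    label: Optional[int] = None,
    dt_tol: float = 1e-6,
    metadata: Optional[dict] = None,
) -> BreathSample:
    """Read a wide trace CSV into a BreathSample.

    Humidity-listed and non-sensor columns are dropped; the time column must
    be uniform within ``dt_tol``; exactly 28 usable sensor columns must
    remain.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path.name}: missing time_s column")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path.name}: ragged/missing values at row {bad}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path.name}: too few rows")
    dts = np.diff(t)
    if np.any(dts <= 0):
        bad = int(np.flatnonzero(dts <= 0)[0]) + 1
        raise FormatError(f"{path.name}: non-monotone time at row {bad}")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > dt_tol:
        raise FormatError(f"{path.name}: non-uniform sampling interval")

    drop = set(humidity_sensor_ids)
    sensor_cols = [
        c for c in df.columns
        if c != "time_s" and c not in drop
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    if len(sensor_cols) != N_ACTIVE_SENSORS:
        raise FormatError(
            f"{path.name}: {len(sensor_cols)} usable sensor columns; "
            f"expected {N_ACTIVE_SENSORS}"
        )
    traces = [
        SensorTrace(sensor_id=c, dt_s=dt, values=df[c].to_numpy(dtype=float))
        for c in sensor_cols
    ]
    return BreathSample(
        sample_id=sample_id or path.stem,
        label=label,
        traces=traces,
        metadata=metadata or {},
    )


def write_cohort(samples: Sequence[BreathSample], out_dir, spec=None) -> Path:
    """One wide CSV per sample plus a manifest CSV (and the spec as JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        write_trace_csv(s, out_dir / f"{s.sample_id}.csv")
        rows.append(
            {
                "sample_id": s.sample_id,
                "label": -1 if s.label is None else s.label,
                "degraded": bool(s.metadata.get("degraded", False)),
                "seed": s.metadata.get("seed_index", -1),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    if spec is not None:
        (out_dir / "cohort_spec.json").write_text(spec.to_json())
    return out_dir


def read_cohort(
    in_dir, humidity_sensor_ids: Sequence[str] = DEFAULT_HUMIDITY_SENSORS
) -> list[BreathSample]:
    """Read a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    samples = []
    for row in manifest.itertuples(index=False):
        label = None if row.label == -1 else int(row.label)
        samples.append(
            read_trace_csv(
                in_dir / f"{row.sample_id}.csv",
                humidity_sensor_ids=humidity_sensor_ids,
                sample_id=str(row.sample_id),
                label=label,
                metadata={"degraded": bool(row.degraded)},
            )
        )
    return samples


def _metric_table(report: dict) -> str:
    has_test = any("test" in report[m] for m in METRIC_NAMES)
    lines = [f"{'Metric':<12}{'Train':>16}{'Validation':>18}"
             + (f"{'Test':>8}" if has_test else "")]
    for m in METRIC_NAMES:
        tr, va = report[m]["train"], report[m]["validation"]
        row = (f"{m.capitalize():<12}"
               f"{tr['mean']:>9.2f} ± {tr['sd']:<4.2f}"
               f"{va['mean']:>11.2f} ± {va['sd']:<4.2f}")
        if has_test:
            row += f"{report[m].get('test', float('nan')):>8.2f}"
        lines.append(row)
    return "\n".join(lines)


def write_report(
    out_dir,
    cv_report: CVReport,
    test_counts: Optional[ConfusionCounts] = None,
    test_metrics: Optional[MetricSet] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Serialize a complete run report.

    Writes ``report.json`` (per-metric train/validation mean±SD and, when a
    holdout was evaluated, the test value), ``metrics.txt`` (human-readable
    table) and ``confusion_validation.csv`` / ``confusion_test.csv``.
    """
    if cv_report is None or not cv_report.per_iteration:
        raise FormatError("partial report: missing cv_report iterations")
    if (test_counts is None) != (test_metrics is None):
        raise FormatError("partial report: test counts and metrics must "
                          "be given together")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metrics: dict = {}
    for m in METRIC_NAMES:
        metrics[m] = {
            "train": dict(cv_report.train_aggregate[m]),
            "validation": dict(cv_report.aggregate[m]),
        }
        if test_metrics is not None:
            metrics[m]["test"] = getattr(test_metrics, m)
    payload = {"metrics": metrics, "cv": cv_report.to_dict()}
    if extra:
        payload["run"] = extra
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    (out_dir / "metrics.txt").write_text(_metric_table(metrics) + "\n")

    val = pd.DataFrame(
        [vars(it.counts) for it in cv_report.per_iteration]
    )
    val.index.name = "iteration"
    val.to_csv(out_dir / "confusion_validation.csv")
    if test_counts is not None:
        pd.DataFrame([vars(test_counts)]).to_csv(
            out_dir / "confusion_test.csv", index=False
        )
    return out_dir
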