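"""Synthetic electronic-nose cohort generator.

Emulates the statistical structure of a polymer-sensor breath study so the
whole pipeline is testable without instrument data: a three-phase measurement
(baseline purge, sample exposure, final purge), per-sensor response scales and
kinetics, class-dependent multiplicative amplitude shifts on a subset of
sensors, additive Gaussian noise, optional linear drift, and a low-SNR
"stale sample" mode in which response amplitudes collapse into the noise.

The response shape is the simplest form consistent with the three-phase
protocol: a saturating-exponential rise toward the class-shifted amplitude
during exposure and an exponential decay back to baseline afterwards.  The
disease effect is multiplicative because polymer-sensor responses scale with
analyte concentration.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .signals import BreathSample, N_ACTIVE_SENSORS, SensorTrace


class ParameterError(ValueError):
    """Invalid generator parameter."""


@dataclass(frozen=True)
class SensorModel:
    """Response model for one polymer sensor.

    base_amplitude is the saturation response (resistance-change units) of a
    healthy-class sample; rise_tau / decay_tau are the exposure and purge time
    constants in seconds; noise_sd is additive Gaussian noise in amplitude
    units; drift_slope is a linear baseline drift in units/second;
    baseline_level is the resting reading (nonzero, so fractional
    normalization is well defined).
    """

    sensor_id: str
    base_amplitude: float
    rise_tau: float
    decay_tau: float
    noise_sd: float = 0.0
    drift_slope: float = 0.0
    baseline_level: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.base_amplitude, self.rise_tau, self.decay_tau,
                self.noise_sd, self.drift_slope, self.baseline_level)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"sensor {self.sensor_id}: non-finite parameter")
        if self.base_amplitude <= 0:
            raise ParameterError("base_amplitude must be > 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ParameterError("time constants must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the measurement protocol the generator emulates: a 25 s
    ambient baseline purge, 40 s of sample exposure, 120 s total at 1 Hz.
    ``effect_size`` is the fractional amplitude shift applied to sick-class
    samples on ``effect_sensors``; ``stale_fraction`` is the proportion of
    samples degraded to low SNR (stale, late-measured samples).
    """

    n_healthy: int
    n_sick: int
    effect_size: float = 0.3
    effect_sensors: tuple[str, ...] = tuple(f"S{i:02d}" for i in range(1, 9))
    stale_fraction: float = 0.0
    duration_s: float = 120.0
    dt_s: float = 1.0
    baseline_s: float = 25.0
    exposure_s: float = 40.0
    seed: int = 0
    stale_snr_factor: float = 0.05

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_sick < 0:
            raise ParameterError("class sizes must be >= 0")
        if not 0.0 <= self.stale_fraction <= 1.0:
            raise ParameterError("stale_fraction must lie in [0, 1]")
        if self.dt_s <= 0:
            raise ParameterError("dt_s must be > 0")
        if self.baseline_s + self.exposure_s >= self.duration_s:
            raise ParameterError("baseline_s + exposure_s must be < duration_s")
        if self.effect_size <= -1.0:
            raise ParameterError("effect_size must be > -1")

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_sick

    def to_json(self) -> str:
        d = asdict(self)
        d["effect_sensors"] = list(self.effect_sensors)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["effect_sensors"] = tuple(d["effect_sensors"])
        return cls(**d)


def default_sensor_bank(
    n_sensors: int = N_ACTIVE_SENSORS,
    noise_rel: float = 0.10,
    seed: int = 2210,
) -> list[SensorModel]:
    """A reproducible bank of heterogeneous sensor models.

    Amplitudes span 0.5-2.0 response units, rise time constants 4-12 s
    (well under the 40 s exposure, so responses saturate), decay constants
    10-30 s.  Noise SD is ``noise_rel`` of each sensor's amplitude — a
    signal-to-noise ratio of 10 at default, generous enough that clean
    samples always clear QC while 20:1-degraded stale samples do not.
    """
    rng = np.random.default_rng(seed)
    bank = []
    for i in range(n_sensors):
        amp = float(rng.uniform(0.5, 2.0))
        bank.append(
            SensorModel(
                sensor_id=f"S{i + 1:02d}",
                base_amplitude=amp,
                rise_tau=float(rng.uniform(4.0, 12.0)),
                decay_tau=float(rng.uniform(10.0, 30.0)),
                noise_sd=noise_rel * amp,
                drift_slope=0.0,
            )
        )
    return bank


def generate_trace(
    model: SensorModel,
    class_shift: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> SensorTrace:
    """Simulate one sensor trace for one measurement.

    Noiseless shape: baseline_level during the purge; a saturating rise
    toward ``base_amplitude * (1 + class_shift)`` with time constant
    ``rise_tau`` during exposure; exponential decay back toward baseline with
    ``decay_tau`` afterwards.  Gaussian noise of SD ``noise_sd`` and linear
    drift ``drift_slope * t`` are added throughout.
    """
    if class_shift <= -1.0:
        raise ParameterError("class_shift must be > -1")
    n = int(round(spec.duration_s / spec.dt_s)) + 1
    t = np.arange(n) * spec.dt_s
    clean = noiseless_trace_values(model, class_shift, spec)
    noise = rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0
    values = clean + model.drift_slope * t + noise
    return SensorTrace(
        sensor_id=model.sensor_id,
        dt_s=spec.dt_s,
        values=values,
        meta={"noise_sd": model.noise_sd},
    )


def noiseless_trace_values(
    model: SensorModel, class_shift: float, spec: CohortSpec
) -> np.ndarray:
    """Deterministic (noise- and drift-free) trace for the given shift."""
    n = int(round(spec.duration_s / spec.dt_s)) + 1
    t = np.arange(n) * spec.dt_s
    t_on = spec.baseline_s
    t_off = spec.baseline_s + spec.exposure_s
    peak_target = model.base_amplitude * (1.0 + class_shift)

    resp = np.zeros(n)
    rising = (t > t_on) & (t <= t_off)
    resp[rising] = peak_target * (1.0 - np.exp(-(t[rising] - t_on) / model.rise_tau))
    r_off = peak_target * (1.0 - math.exp(-spec.exposure_s / model.rise_tau))
    after = t > t_off
    resp[after] = r_off * np.exp(-(t[after] - t_off) / model.decay_tau)
    return model.baseline_level + resp


def sample_seed(master_seed: int, index: int) -> np.random.Generator:
    """Per-sample RNG stream, stable under cohort-size changes."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return np.random.default_rng(ss)


def generate_sample(
    spec: CohortSpec,
    sensor_bank: Sequence[SensorModel],
    index: int,
    label: int,
) -> BreathSample:
    """One labeled sample; sick samples carry the effect on effect_sensors."""
    rng = sample_seed(spec.seed, index)
    effect = set(spec.effect_sensors)
    traces = []
    for model in sensor_bank:
        shift = spec.effect_size if (label == 1 and model.sensor_id in effect) else 0.0
        traces.append(generate_trace(model, shift, spec, rng))
    return BreathSample(
        sample_id=f"sample_{index:04d}",
        label=label,
        traces=traces,
        metadata={"degraded": False, "seed_index": index},
    )


def degrade_sample(
    sample: BreathSample,
    snr_factor: float,
    rng: Optional[np.random.Generator] = None,
) -> BreathSample:
    """Collapse a sample's response amplitudes to emulate a stale measurement.

    Each trace's deviation from its baseline mean is scaled by ``snr_factor``
    while the noise level is held fixed: when the generating noise SD is
    known (synthetic traces record it in ``meta``), scaling shrinks the noise
    by ``snr_factor`` too, so compensating Gaussian noise of SD
    ``noise_sd * sqrt(1 - snr_factor**2)`` is added back.
    """
    if not 0.0 < snr_factor < 1.0:
        raise ParameterError("snr_factor must lie strictly in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    new_traces = []
    for tr in sample.traces:
        n_base = max(int(round(25.0 / tr.dt_s)), 2)
        base_mean = float(np.mean(tr.values[: min(n_base, len(tr))]))
        scaled = base_mean + snr_factor * (tr.values - base_mean)
        noise_sd = tr.meta.get("noise_sd", 0.0)
        if noise_sd > 0:
            top_up = rng.normal(
                0.0, noise_sd * math.sqrt(1.0 - snr_factor**2), size=len(tr)
            )
            scaled = scaled + top_up
        new_traces.append(replace(tr, values=scaled))
    return BreathSample(
        sample_id=sample.sample_id,
        label=sample.label,
        traces=new_traces,
        qc_state="unchecked",
        metadata={**sample.metadata, "degraded": True, "snr_factor": snr_factor},
    )


def generate_cohort(
    spec: CohortSpec,
    sensor_bank: Optional[Sequence[SensorModel]] = None,
) -> list[BreathSample]:
    """Generate a full labeled cohort.

    Healthy samples (label 0) come first, then sick (label 1).  The first
    ``floor(stale_fraction * n_total)`` samples in a seed-shuffled order are
    degraded to low SNR.  Per-sample RNG streams are spawned from
    ``spec.seed`` by sample index, so enlarging the cohort never reshuffles
    earlier samples.
    """
    if sensor_bank is None:
        sensor_bank = default_sensor_bank()
    if len(sensor_bank) != N_ACTIVE_SENSORS:
        raise ParameterError(
            f"sensor_bank has {len(sensor_bank)} models; expected "
            f"{N_ACTIVE_SENSORS} active sensors"
        )
    labels = [0] * spec.n_healthy + [1] * spec.n_sick
    samples = [
        generate_sample(spec, sensor_bank, index=i, label=lab)
        for i, lab in enumerate(labels)
    ]
    n_stale = int(math.floor(spec.stale_fraction * spec.n_total))
    if n_stale > 0:
        order_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(10**6,))
        )
        stale_idx = order_rng.permutation(spec.n_total)[:n_stale]
        for i in stale_idx:
            degrade_rng = sample_seed(spec.seed, int(i) + 2 * 10**6)
            samples[int(i)] = degrade_sample(
                samples[int(i)], spec.stale_snr_factor, degrade_rng
            )
    return samples
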