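"""Synthetic breath waveforms and forward-simulated acquisitions.

Stands in for the hardware: generates ground-truth flow waveforms
(calibration-pump strokes and forced expirations) and pushes them
through the forward physics + electronics chain (Venturi dp + wall
friction -> sensor voltage -> noise/drift -> divider -> ADC) to produce
raw count traces identical in form to a serial capture.

Every generated waveform is renormalised so its trapezoidal integral
equals the requested volume exactly (to ~1e-6 L), which makes the
generator usable as a volume oracle for end-to-end recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .acquisition_model import (
    AcquisitionConfig,
    AdcSpec,
    DividerSpec,
    SensorSpec,
    adc_quantize,
    divider_down,
    sensor_voltage_from_pressure,
)
from .breath_pipeline import RawTrace
from .venturi_core import (
    M3S_PER_LPM,
    FluidProperties,
    TubeGeometry,
    dp_from_flow,
    friction_pressure_drop,
)

__all__ = [
    "StrokeSpec",
    "ExpirationSpec",
    "NoiseModel",
    "Waveform",
    "pump_stroke_flow",
    "forced_expiration_flow",
    "simulate_acquisition",
    "write_trace",
    "read_trace",
    "TraceParseError",
]


class TraceParseError(ValueError):
    """Malformed serial-capture CSV."""


@dataclass(frozen=True)
class StrokeSpec:
    """One calibration-pump stroke.

    The hand-pump experiments expel a fixed 2 L volume over strokes of
    0.3-2.5 s; ``half_sine`` is the default shape (smooth start/stop of
    a hand-compressed pump, closed-form peak pi*V/(2T)).
    """

    volume_l: float = 2.0
    duration_s: float = 1.0
    shape: str = "half_sine"
    lead_in_s: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValueError("volume must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.shape not in ("half_sine", "trapezoid"):
            raise ValueError(f"unknown stroke shape {self.shape!r}")
        if self.lead_in_s < 0:
            raise ValueError("lead_in must be >= 0")


@dataclass(frozen=True)
class ExpirationSpec:
    """Forced-expiration morphology: linear rise to PEF, exponential decay.

    ``decay_constant_s`` is solved numerically so the realized integral
    equals ``fvc_l``; a supplied value is used only as the solver's
    initial bracket centre.
    """

    pef_lpm: float = 600.0
    fvc_l: float = 4.0
    rise_time_s: float = 0.1
    decay_constant_s: Optional[float] = None
    lead_in_s: float = 1.0

    def __post_init__(self) -> None:
        if self.pef_lpm <= 0 or self.fvc_l <= 0 or self.rise_time_s <= 0:
            raise ValueError("pef, fvc and rise_time must be > 0")
        pef_ls = self.pef_lpm / 60.0
        if pef_ls * self.rise_time_s / 2.0 > self.fvc_l:
            raise ValueError(
                "infeasible expiration: rise-phase volume "
                f"{pef_ls * self.rise_time_s / 2.0:.2f} L already exceeds "
                f"FVC {self.fvc_l} L"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition imperfections applied sensor-side.

    ``voltage_noise_sigma`` is Gaussian noise on the sensor output
    voltage (default 5 mV, about half an ADC step after the divider);
    drift is a linear baseline ramp; hysteresis, when enabled, is a
    bounded direction-dependent perturbation within the datasheet
    budget.  Identical seeds give byte-identical traces.
    """

    voltage_noise_sigma: float = 0.005
    offset_drift_rate: float = 0.0
    quantization: bool = True
    hysteresis_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voltage_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class Waveform:
    """Ground-truth flow waveform plus the metadata needed to score recovery."""

    time_s: np.ndarray
    flow_m3s: np.ndarray
    sampling_rate: float
    truth: dict = field(default_factory=dict)

    @property
    def flow_lpm(self) -> np.ndarray:
        return self.flow_m3s / M3S_PER_LPM


def _renormalise(flow: np.ndarray, dt: float, volume_m3: float) -> np.ndarray:
    integral = np.trapezoid(flow, dx=dt)
    if integral <= 0:
        raise ValueError("degenerate waveform: zero integral")
    return flow * (volume_m3 / integral)


def pump_stroke_flow(spec: StrokeSpec, sampling_rate: float = 1000.0) -> Waveform:
    """Generate one pump stroke: quiet lead-in then a single expulsion.

    The stroke is renormalised so its trapezoidal integral equals the
    requested volume to ~1e-6 L, making the spec a volume oracle.
    """
    dt = 1.0 / sampling_rate
    n_stroke = int(round(spec.duration_s * sampling_rate))
    if n_stroke < 2:
        raise ValueError(
            f"duration {spec.duration_s} s spans fewer than 2 samples at "
            f"{sampling_rate} Hz"
        )
    n_lead = int(round(spec.lead_in_s * sampling_rate))
    ts = np.arange(n_stroke + 1) * dt
    if spec.shape == "half_sine":
        # sample rounding can push the last grid point past T; clamp at 0
        stroke = np.maximum(np.sin(np.pi * ts / spec.duration_s), 0.0)
    else:  # trapezoid: 25% ramp up, 50% plateau, 25% ramp down
        ramp = spec.duration_s * 0.25
        stroke = np.minimum(
            1.0, np.minimum(ts / ramp, (spec.duration_s - ts) / ramp)
        )
        stroke = np.maximum(stroke, 0.0)
    stroke = _renormalise(stroke, dt, spec.volume_l * 1e-3)
    n_tail = int(round(0.5 * sampling_rate))  # quiet tail for segmentation
    flow = np.concatenate([np.zeros(n_lead), stroke, np.zeros(n_tail)])
    t = np.arange(flow.size) * dt
    truth = {
        "volume_l": spec.volume_l,
        "duration_s": spec.duration_s,
        "pef_lpm": float(np.max(flow) / M3S_PER_LPM),
        "shape": spec.shape,
    }
    return Waveform(t, flow, sampling_rate, truth)


def forced_expiration_flow(
    spec: ExpirationSpec, sampling_rate: float = 1000.0
) -> Waveform:
    """Generate a forced-expiration waveform with exact PEF and FVC.

    Linear rise to PEF over ``rise_time_s`` followed by exponential
    decay; the decay constant is solved (Brent's method) so the
    realized trapezoidal integral equals ``fvc_l`` within ~1e-9 L while
    the waveform maximum stays exactly at PEF.  The ground-truth FEV1
    (integral over the first second from exhalation onset) is recorded
    in ``truth``.
    """
    dt = 1.0 / sampling_rate
    pef_m3s = spec.pef_lpm * M3S_PER_LPM
    fvc_m3 = spec.fvc_l * 1e-3
    n_rise = max(int(round(spec.rise_time_s * sampling_rate)), 2)
    rise = np.linspace(0.0, pef_m3s, n_rise + 1)

    def _decay(tau: float) -> np.ndarray:
        # decay until flow < 0.1% of PEF (cap 30 s)
        t_end = min(-tau * np.log(1e-3), 30.0)
        n = max(int(np.ceil(t_end * sampling_rate)), 2)
        return pef_m3s * np.exp(-np.arange(1, n + 1) * dt / tau)

    def _volume_err(tau: float) -> float:
        flow = np.concatenate([rise, _decay(tau)])
        return float(np.trapezoid(flow, dx=dt)) - fvc_m3

    lo, hi = 1e-3, 60.0
    if _volume_err(hi) < 0:
        raise ValueError("FVC unreachable with this PEF/rise time")
    tau = brentq(_volume_err, lo, hi, xtol=1e-10)
    exhal = np.concatenate([rise, _decay(tau)])
    n_lead = int(round(spec.lead_in_s * sampling_rate))
    flow = np.concatenate([np.zeros(n_lead), exhal])
    t = np.arange(flow.size) * dt
    n_1s = int(round(sampling_rate))
    fev1 = float(np.trapezoid(exhal[: n_1s + 1], dx=dt)) * 1e3
    truth = {
        "pef_lpm": spec.pef_lpm,
        "fvc_l": spec.fvc_l,
        "fev1_l": min(fev1, spec.fvc_l),
        "decay_constant_s": float(tau),
        "duration_s": exhal.size * dt,
    }
    return Waveform(t, flow, sampling_rate, truth)


def simulate_acquisition(
    waveform: Waveform,
    geom: TubeGeometry = TubeGeometry(),
    fluid: FluidProperties = FluidProperties(),
    sensor: SensorSpec = SensorSpec(),
    divider: DividerSpec = DividerSpec(),
    adc: AdcSpec = AdcSpec(),
    acq: AcquisitionConfig = AcquisitionConfig(),
    noise: NoiseModel = NoiseModel(),
) -> RawTrace:
    """Run a flow waveform through the forward sensor chain.

    Per sample: dp = Venturi dp + wall-friction loss; sensor voltage via
    the affine transfer function (with its 0.2 V zero-pressure offset);
    plus linear drift and seeded Gaussian noise; then divider + ADC
    quantization (or exact fractional counts when ``quantization`` is
    off, for oracle tests).  The trace is padded with quiet baseline or
    truncated to ``acq.n_samples``.
    """
    q = np.asarray(waveform.flow_m3s, dtype=float)
    n = acq.n_samples
    if q.size < n:
        q = np.concatenate([q, np.zeros(n - q.size)])
    elif q.size > n:
        warnings.warn(
            f"waveform of {q.size} samples truncated to {n}", stacklevel=2
        )
        q = q[:n]
    dp = dp_from_flow(q, geom, fluid) + friction_pressure_drop(q, geom, fluid)
    n_clipped = int(np.count_nonzero(dp > sensor.pressure_range))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clip warning folded into meta
        v = sensor_voltage_from_pressure(dp, sensor)
    t = np.arange(n) / acq.sampling_rate
    rng = np.random.default_rng(noise.seed)
    v = v + noise.offset_drift_rate * t
    if noise.voltage_noise_sigma > 0:
        v = v + rng.normal(0.0, noise.voltage_noise_sigma, size=n)
    if noise.hysteresis_enabled:
        # bounded direction-dependent perturbation within the datasheet budget
        direction = np.sign(np.gradient(dp))
        v = v + direction * 0.5 * sensor.hysteresis_fss_fraction * sensor.full_scale_voltage
    v = np.maximum(v, 0.0)
    if noise.quantization:
        counts = adc_quantize(v, adc, divider)
    else:
        counts = divider_down(v, divider) * adc.max_count / adc.reference_voltage
        counts = np.clip(counts, 0.0, float(adc.max_count))
    return RawTrace(
        counts=counts,
        sampling_rate=acq.sampling_rate,
        meta={"n_pressure_clipped": n_clipped, "seed": noise.seed,
              "truth": dict(waveform.truth)},
    )


def write_trace(path, trace: RawTrace) -> None:
    """Write a trace as serial-capture CSV (columns ``t_ms, counts``)."""
    t_ms = np.arange(len(trace)) * (1000.0 / trace.sampling_rate)
    df = pd.DataFrame({"t_ms": t_ms, "counts": trace.counts})
    df.to_csv(path, index=False)


def read_trace(path, sampling_rate: float = 1000.0) -> RawTrace:
    """Read a serial-capture CSV.

    Accepts either a ``t_ms`` column (sampling rate inferred from the
    timestamp spacing) or a ``sample_index`` column (``sampling_rate``
    argument used).  A header line is required; malformed files raise
    :class:`TraceParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise TraceParseError(f"{path}: unreadable CSV ({exc})") from exc
    cols = set(df.columns)
    if "counts" not in cols or not ({"t_ms", "sample_index"} & cols):
        raise TraceParseError(
            f"{path}: header must contain 'counts' and one of "
            f"'t_ms'/'sample_index' (line 1), got {sorted(cols)}"
        )
    counts = df["counts"].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        bad = int(np.nonzero(~pd.to_numeric(df["counts"], errors="coerce").notna())[0][0])
        raise TraceParseError(f"{path}: non-numeric counts at line {bad + 2}")
    if "t_ms" in cols:
        t_ms = df["t_ms"].to_numpy(dtype=float)
        if t_ms.size > 1:
            dt_ms = float(np.median(np.diff(t_ms)))
            if dt_ms <= 0:
                raise TraceParseError(f"{path}: non-increasing t_ms column")
            sampling_rate = 1000.0 / dt_ms
    return RawTrace(counts=counts, sampling_rate=sampling_rate)
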