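"""Forward and inverse model of the electronics chain.

The signal path is: differential pressure -> MPX5010-class analogue
sensor (ratiometric affine transfer, 0.2 V offset at zero pressure)
-> resistive voltage divider (4.7 kOhm over 10 kOhm, factor 1/1.47,
protecting the 3.3 V analogue input) -> 12-bit ADC.  The simulator runs
the chain forward; the processing pipeline runs it backward, rescaling
counts to the sensor-side voltage and subtracting the calibrated
offset.

The sensor transfer function is the published MPX5010 characteristic
V = Vs * (0.09 * P_kPa + 0.04); the datasheet accuracy / linearity /
hysteresis figures are carried as fractions of full-scale span so the
simulator can use them as perturbation budgets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensorSpec",
    "DividerSpec",
    "AdcSpec",
    "AcquisitionConfig",
    "sensor_voltage_from_pressure",
    "pressure_from_voltage",
    "divider_down",
    "counts_to_voltage",
    "adc_quantize",
]

#: sensor sensitivity, output fraction of supply per kPa
SENSOR_SENSITIVITY_PER_KPA = 0.09
#: zero-pressure output as a fraction of supply
SENSOR_OFFSET_FRACTION = 0.04


class SensorDomainError(ValueError):
    """Negative pressure or other inadmissible sensor input."""


class CountsRangeError(ValueError):
    """ADC counts outside [0, n_levels - 1]."""

    def __init__(self, indices):
        self.indices = indices
        super().__init__(f"ADC counts out of range at sample indices {indices}")


@dataclass(frozen=True)
class SensorSpec:
    """Analogue differential-pressure sensor (MPX5010-class) parameters.

    Error-budget fractions are relative to full-scale span (FSS):
    accuracy +/-5% of the 4.5 V span (+/-0.225 V), linearity 0.2% of
    span (0.02 kPa), hysteresis 0.1% (10 Pa over the 10 kPa range).
    """

    supply_voltage: float = 5.0
    pressure_range: float = 10_000.0
    max_output_voltage: float = 4.7
    accuracy_fss_fraction: float = 0.05
    full_scale_voltage: float = 4.5
    linearity_fss_fraction: float = 0.002
    hysteresis_fss_fraction: float = 0.001
    response_time: float = 0.001
    offset_voltage_nominal: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.max_output_voltage <= self.supply_voltage:
            raise ValueError("require 0 < max_output_voltage <= supply_voltage")
        for name in (
            "accuracy_fss_fraction",
            "linearity_fss_fraction",
            "hysteresis_fss_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def sensitivity_v_per_pa(self) -> float:
        """Slope of the ideal transfer curve, V/Pa."""
        return self.supply_voltage * SENSOR_SENSITIVITY_PER_KPA / 1000.0

    @property
    def accuracy_band_v(self) -> float:
        """Absolute accuracy band, V (fraction of full-scale voltage)."""
        return self.accuracy_fss_fraction * self.full_scale_voltage

    @property
    def hysteresis_band_pa(self) -> float:
        """Hysteresis bound expressed in pressure units, Pa."""
        return self.hysteresis_fss_fraction * self.pressure_range

    @property
    def linearity_band_pa(self) -> float:
        """Linearity bound expressed in pressure units, Pa."""
        return self.linearity_fss_fraction * self.pressure_range


@dataclass(frozen=True)
class DividerSpec:
    """Resistive divider scaling the sensor output into the ADC range."""

    r_top: float = 4700.0
    r_bottom: float = 10_000.0

    def __post_init__(self) -> None:
        if self.r_top <= 0 or self.r_bottom <= 0:
            raise ValueError("resistor values must be > 0")

    @property
    def scale_down_factor(self) -> float:
        """(r_top + r_bottom) / r_bottom; 1.47 for 4.7k over 10k."""
        return (self.r_top + self.r_bottom) / self.r_bottom


@dataclass(frozen=True)
class AdcSpec:
    """Successive-approximation ADC on the microcontroller analogue pin."""

    reference_voltage: float = 3.3
    n_levels: int = 4096

    def __post_init__(self) -> None:
        if self.reference_voltage <= 0 or self.n_levels < 2:
            raise ValueError("invalid ADC spec")

    @property
    def resolution(self) -> float:
        """Nominal volts per step, reference_voltage / n_levels (~0.805 mV)."""
        return self.reference_voltage / self.n_levels

    @property
    def max_count(self) -> int:
        return self.n_levels - 1


@dataclass(frozen=True)
class AcquisitionConfig:
    """Serial-capture parameters: 1 kHz for 10,000 samples (>10 s)."""

    sampling_rate: float = 1000.0
    n_samples: int = 10_000

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ValueError(
                "sampling_rate must be >= 100 Hz (spirometry technical minimum)"
            )
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")


def sensor_voltage_from_pressure(p, spec: SensorSpec = SensorSpec()):
    """Ideal (noise-free) sensor output voltage for pressure ``p`` (Pa).

    V = Vs * (0.09 * P_kPa + 0.04); affine and increasing in p.
    Pressures above the rated range clip to the range with a warning
    (mirroring hardware saturation); negative pressures raise.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise SensorDomainError("pressure must be >= 0 (differential port order)")
    n_over = int(np.count_nonzero(arr > spec.pressure_range))
    if n_over:
        warnings.warn(
            f"{n_over} pressure sample(s) above the {spec.pressure_range:.0f} Pa "
            "sensor range were clipped",
            stacklevel=2,
        )
        arr = np.minimum(arr, spec.pressure_range)
    v = spec.supply_voltage * (
        SENSOR_SENSITIVITY_PER_KPA * arr / 1000.0 + SENSOR_OFFSET_FRACTION
    )
    return float(v) if np.ndim(p) == 0 else v


def pressure_from_voltage(v, spec: SensorSpec = SensorSpec(), offset: float = 0.2):
    """Invert the sensor transfer function.

    ``offset`` is the calibrated zero-pressure voltage (sensor side).
    Negative reconstructed pressures are clamped to zero -- baseline
    noise straddles the offset -- and the clamp count is returned.

    Returns
    -------
    (pressure, n_clamped)
        Pressure in Pa (same shape as ``v``) and how many samples were
        clamped at zero.
    """
    arr = np.asarray(v, dtype=float)
    p = (arr - offset) / spec.sensitivity_v_per_pa
    n_clamped = int(np.count_nonzero(p < 0))
    p = np.maximum(p, 0.0)
    if np.ndim(v) == 0:
        return float(p), n_clamped
    return p, n_clamped


def divider_down(v, spec: DividerSpec = DividerSpec()):
    """Voltage after the divider: v * r_bottom / (r_top + r_bottom)."""
    arr = np.asarray(v, dtype=float)
    out = arr * spec.r_bottom / (spec.r_top + spec.r_bottom)
    return float(out) if np.ndim(v) == 0 else out


def counts_to_voltage(
    counts,
    adc: AdcSpec = AdcSpec(),
    divider: DividerSpec = DividerSpec(),
):
    """Reconstruct the sensor-side voltage from ADC counts.

    V = counts * (reference_voltage / (n_levels - 1)) * scale_down_factor,
    so full-scale counts map exactly to the reference voltage before the
    divider rescale.  Counts outside [0, n_levels - 1] raise
    :class:`CountsRangeError` naming the offending sample indices.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 0:
        if arr < 0 or arr > adc.max_count:
            raise CountsRangeError([0])
    else:
        bad = np.nonzero((arr < 0) | (arr > adc.max_count))[0]
        if bad.size:
            raise CountsRangeError(bad[:10].tolist())
    v = arr * (adc.reference_voltage / adc.max_count) * divider.scale_down_factor
    return float(v) if np.ndim(counts) == 0 else v


def adc_quantize(
    v,
    adc: AdcSpec = AdcSpec(),
    divider: DividerSpec = DividerSpec(),
):
    """Quantize a sensor-side voltage into ADC counts.

    Applies the divider, rounds to the nearest count and clips to
    [0, n_levels - 1]; the pre-clipping quantization error is at most
    half an LSB.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise SensorDomainError("sensor-side voltage must be >= 0")
    divided = divider_down(arr, divider)
    counts = np.rint(divided * adc.max_count / adc.reference_voltage)
    counts = np.clip(counts, 0, adc.max_count).astype(np.int64)
    return int(counts) if np.ndim(v) == 0 else counts
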