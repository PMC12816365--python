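"""Fluid physics of a Venturi flow tube.

A Venturi tube converts a volumetric flow into a differential pressure
between its wide entrance and narrow throat.  For an incompressible,
inviscid fluid the Bernoulli/continuity solution is

    Q = A_t * sqrt( 2 * dp / (rho * (1 - (A_t / A_e)**2)) )

with ``A_t`` the throat cross-section and ``A_e`` the entrance
cross-section.  This module provides that conversion and its exact
inverse, Reynolds-number flow-regime analysis, a Darcy-Weisbach wall
friction correction, and a compliance check against the British
Standards dimensional constraints for classical Venturi tubes.

All operations use SI units internally (m, m^3/s, Pa); flow sweeps and
reports that mirror spirometry practice use L/min at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "M3S_PER_LPM",
    "FluidProperties",
    "TubeGeometry",
    "FlowRegimeResult",
    "GeometryComplianceReport",
    "flow_from_dp",
    "dp_from_flow",
    "reynolds_number",
    "transition_flow",
    "friction_pressure_drop",
    "check_bs_venturi_spec",
    "max_drag_fraction",
]

#: conversion factor, m^3/s per L/min
M3S_PER_LPM = 1e-3 / 60.0


class VenturiDomainError(ValueError):
    """Raised for physically inadmissible inputs (e.g. negative dp)."""


@dataclass(frozen=True)
class FluidProperties:
    """Fluid constants for air at 20 degC / 101.325 kPa.

    Parameters
    ----------
    density : float
        Mass density rho, kg/m^3.
    viscosity : float
        Dynamic viscosity mu, kg/(m s).
    """

    density: float = 1.204
    viscosity: float = 1.81e-5

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class TubeGeometry:
    """Dimensions of the printed Venturi tube.

    Defaults are the as-printed diameters (the FDM nozzle undersizes the
    designed 28 mm / 10 mm bores to 27.8 mm / 9.8 mm).  Section lengths
    for the friction model default to one entrance diameter (entrance
    run) and 1.5 throat diameters (throat run) when not supplied.
    Angles are in degrees.
    """

    entrance_diameter: float = 0.0278
    throat_diameter: float = 0.0098
    entrance_length: Optional[float] = None
    throat_length: Optional[float] = None
    convergent_angle: float = 10.0
    divergent_angle: float = 7.5
    divergent_length: Optional[float] = None
    wall_roughness: float = 10e-6

    def __post_init__(self) -> None:
        if not 0 < self.throat_diameter < self.entrance_diameter:
            raise ValueError(
                "require 0 < throat_diameter < entrance_diameter, got "
                f"{self.throat_diameter} / {self.entrance_diameter}"
            )
        for name in ("entrance_length", "throat_length", "divergent_length"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.wall_roughness < 0:
            raise ValueError("wall_roughness must be >= 0")

    @property
    def entrance_area(self) -> float:
        """Entrance cross-section A_e = pi d^2 / 4, m^2."""
        return math.pi * self.entrance_diameter**2 / 4.0

    @property
    def throat_area(self) -> float:
        """Throat cross-section A_t = pi d^2 / 4, m^2."""
        return math.pi * self.throat_diameter**2 / 4.0

    @property
    def effective_entrance_length(self) -> float:
        """Entrance run used by the friction model, m."""
        if self.entrance_length is not None:
            return self.entrance_length
        return self.entrance_diameter

    @property
    def effective_throat_length(self) -> float:
        """Throat run used by the friction model, m."""
        if self.throat_length is not None:
            return self.throat_length
        return 1.5 * self.throat_diameter

    @property
    def effective_divergent_length(self) -> float:
        if self.divergent_length is not None:
            return self.divergent_length
        return 1.5 * self.throat_diameter


@dataclass(frozen=True)
class FlowRegimeResult:
    """Outcome of a laminar->turbulent transition sweep.

    ``transition_flow_lpm`` is None when no swept flow within
    ``sweep_max_lpm`` exceeds the Reynolds threshold.
    """

    transition_flow_lpm: Optional[float]
    reynolds_at_transition: Optional[float]
    sweep_step_lpm: float
    sweep_max_lpm: float
    re_threshold: float = 2000.0

    @property
    def transitions(self) -> bool:
        return self.transition_flow_lpm is not None


@dataclass(frozen=True)
class GeometryComplianceReport:
    """Per-check outcome of the BS Venturi dimensional constraints."""

    throat_ratio_ok: bool
    convergent_taper_ok: bool
    divergent_angle_ok: bool
    divergent_length_ok: bool
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            self.throat_ratio_ok
            and self.convergent_taper_ok
            and self.divergent_angle_ok
            and self.divergent_length_ok
        )


def _beta_sq(geom: TubeGeometry) -> float:
    # (A_t / A_e)^2, the area-ratio term of the Bernoulli solution
    return (geom.throat_area / geom.entrance_area) ** 2


def flow_from_dp(
    dp,
    geom: TubeGeometry,
    fluid: FluidProperties = FluidProperties(),
    discharge_coefficient: float = 1.0,
):
    """Volumetric flow (m^3/s) from a Venturi differential pressure (Pa).

    Implements the ideal Bernoulli/continuity solution with the throat
    area outside the radical and the squared throat/entrance area ratio
    inside it; an optional discharge coefficient multiplies the ideal
    flow (default 1.0, i.e. no empirical correction).

    Accepts scalars or arrays; negative pressures raise
    :class:`VenturiDomainError` (they indicate reversed port wiring or a
    sub-baseline reading -- callers clamp after offset removal).
    """
    arr = np.asarray(dp, dtype=float)
    if np.any(arr < 0):
        raise VenturiDomainError(
            "negative differential pressure: reversed ports or sub-baseline "
            "reading; clamp to zero before conversion"
        )
    q = discharge_coefficient * geom.throat_area * np.sqrt(
        2.0 * arr / (fluid.density * (1.0 - _beta_sq(geom)))
    )
    return float(q) if arr.ndim == 0 else q


def dp_from_flow(
    q,
    geom: TubeGeometry,
    fluid: FluidProperties = FluidProperties(),
    discharge_coefficient: float = 1.0,
):
    """Differential pressure (Pa) from volumetric flow (m^3/s).

    Exact algebraic inverse of :func:`flow_from_dp`; quadratic and
    strictly monotone in ``q``.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise VenturiDomainError("flow must be >= 0")
    v_throat = arr / (discharge_coefficient * geom.throat_area)
    dp = fluid.density * (1.0 - _beta_sq(geom)) * v_throat**2 / 2.0
    return float(dp) if arr.ndim == 0 else dp


def reynolds_number(q, diameter: float, fluid: FluidProperties = FluidProperties()):
    """Pipe Reynolds number for volumetric flow ``q`` (m^3/s).

    Re = rho v d / mu with v = q / (pi d^2 / 4), i.e.
    Re = 4 rho q / (pi d mu); linear in q.
    """
    if diameter <= 0:
        raise VenturiDomainError(f"diameter must be > 0, got {diameter}")
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise VenturiDomainError("flow must be >= 0")
    re = 4.0 * fluid.density * arr / (math.pi * diameter * fluid.viscosity)
    return float(re) if arr.ndim == 0 else re


def transition_flow(
    diameter: float,
    fluid: FluidProperties = FluidProperties(),
    re_threshold: float = 2000.0,
    step_lpm: float = 0.1,
    sweep_max_lpm: float = 50.0,
) -> FlowRegimeResult:
    """Find the laminar->turbulent transition flow by a discrete sweep.

    Sweeps volumetric flow over ascending multiples of ``step_lpm`` from
    0 to ``sweep_max_lpm`` (L/min) and returns the first swept value
    whose Reynolds number strictly exceeds ``re_threshold``.
    """
    if step_lpm <= 0:
        raise ValueError("step_lpm must be > 0")
    if sweep_max_lpm < step_lpm:
        raise ValueError("sweep_max_lpm must be >= step_lpm")
    n_steps = int(math.floor(sweep_max_lpm / step_lpm + 1e-9))
    flows_lpm = np.arange(n_steps + 1) * step_lpm
    re = reynolds_number(flows_lpm * M3S_PER_LPM, diameter, fluid)
    above = np.nonzero(re > re_threshold)[0]
    if len(above) == 0:
        return FlowRegimeResult(None, None, step_lpm, sweep_max_lpm, re_threshold)
    i = int(above[0])
    # round away accumulated float error so 139 * 0.1 reports as 13.9
    q_lpm = round(float(flows_lpm[i]), 10)
    return FlowRegimeResult(q_lpm, float(re[i]), step_lpm, sweep_max_lpm, re_threshold)


def _haaland_friction_factor(re, relative_roughness: float):
    """Explicit Haaland approximation to the Colebrook friction factor."""
    return (
        -1.8 * np.log10((relative_roughness / 3.7) ** 1.11 + 6.9 / re)
    ) ** -2.0


def friction_pressure_drop(
    q,
    geom: TubeGeometry,
    fluid: FluidProperties = FluidProperties(),
):
    """Wall-friction pressure loss (Pa) over the instrumented sections.

    Darcy-Weisbach ``dp = f (L/d) rho v^2 / 2`` summed over the entrance
    and throat runs, with the friction factor from the Haaland explicit
    correlation above Re = 2000 and the laminar ``64/Re`` law below.
    Relative roughness is ``wall_roughness / diameter`` per section.
    Returns 0 at q = 0 and is monotone increasing in q.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise VenturiDomainError("flow must be >= 0")
    total = np.zeros_like(arr)
    sections = (
        (geom.entrance_diameter, geom.effective_entrance_length),
        (geom.throat_diameter, geom.effective_throat_length),
    )
    for d, length in sections:
        if length == 0:
            continue
        area = math.pi * d**2 / 4.0
        v = arr / area
        re = fluid.density * v * d / fluid.viscosity
        f = np.zeros_like(arr)
        laminar = (re > 0) & (re < 2000.0)
        turbulent = re >= 2000.0
        f[laminar] = 64.0 / re[laminar]
        if np.any(turbulent):
            f[turbulent] = _haaland_friction_factor(
                re[turbulent], geom.wall_roughness / d
            )
        total = total + f * (length / d) * fluid.density * v**2 / 2.0
    return float(total) if arr.ndim == 0 else total


def max_drag_fraction(
    geom: TubeGeometry,
    fluid: FluidProperties = FluidProperties(),
    q_min_lpm: float = 15.0,
    q_max_lpm: float = 600.0,
    n: int = 200,
) -> float:
    """Largest friction/Venturi pressure ratio over a flow range.

    The friction term is meant to be a correction, not the dominant
    pressure.  For the as-printed tube it peaks at ~8% just above the
    laminar->turbulent transition (where the Haaland factor is largest)
    and falls below 5% beyond ~70 L/min; configurations exceeding ~10%
    anywhere in the turbulent working range should be treated as
    suspect.

    The default range starts above the ~14 L/min throat transition: in
    the laminar regime the friction term scales linearly in q while the
    Venturi dp scales quadratically, so their ratio diverges as q -> 0
    even though both terms are then far below one ADC step and
    spirometrically irrelevant.
    """
    q = np.linspace(q_min_lpm, q_max_lpm, n) * M3S_PER_LPM
    ratio = friction_pressure_drop(q, geom, fluid) / dp_from_flow(q, geom, fluid)
    return float(np.max(ratio))


def check_bs_venturi_spec(geom: TubeGeometry) -> GeometryComplianceReport:
    """Check the tube against the BS classical-Venturi dimensional rules.

    * throat diameter >= 0.224 x entrance diameter,
    * convergent taper within 10 +/- 5 degrees,
    * divergent outlet angle >= 5 degrees,
    * divergent section length >= 1.5 x throat diameter.
    """
    ratio = geom.throat_diameter / geom.entrance_diameter
    throat_ok = ratio >= 0.224
    conv_ok = 5.0 <= geom.convergent_angle <= 15.0
    div_angle_ok = geom.divergent_angle >= 5.0
    div_len = geom.effective_divergent_length
    div_len_ok = div_len >= 1.5 * geom.throat_diameter
    details = {
        "throat_ratio": {"measured": ratio, "bound": 0.224, "ok": throat_ok},
        "convergent_taper_deg": {
            "measured": geom.convergent_angle,
            "bound": [5.0, 15.0],
            "ok": conv_ok,
        },
        "divergent_angle_deg": {
            "measured": geom.divergent_angle,
            "bound": 5.0,
            "ok": div_angle_ok,
        },
        "divergent_length_m": {
            "measured": div_len,
            "bound": 1.5 * geom.throat_diameter,
            "ok": div_len_ok,
        },
    }
    return GeometryComplianceReport(throat_ok, conv_ok, div_angle_ok, div_len_ok, details)
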