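"""Closed-form physico-chemical calculators around the fence experiment.

* Helmholtz-Smoluchowski zeta potential from a streaming-potential slope.
* alamarBlue (resazurin) percent reduction and relative initial adhesion.
* The electric-fence voltage sanity rule V = I*R.
* Cell radius from an optically measured spread area, rc = sqrt(Ac/pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "VACUUM_PERMITTIVITY",
    "ZetaInputs",
    "PlateReadings",
    "FenceSchedule",
    "zeta_potential",
    "alamar_reduction",
    "relative_adhesion",
    "ef_voltage",
    "radius_from_area",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m


@dataclass(frozen=True)
class ZetaInputs:
    """Inputs of the Helmholtz-Smoluchowski formula, SI units.

    Defaults describe 10 mM NaCl at 25 C (viscosity 8.9e-4 Pa*s,
    conductivity 0.1265 S/m, relative permittivity 78.5) — the electrolyte
    constants the streaming-potential instrument assumes are rarely printed,
    so these are documented assumptions.
    """

    dE_dP: float  # streaming-potential slope, V/Pa
    viscosity: float = 8.9e-4  # Pa*s
    conductivity: float = 0.1265  # S/m
    rel_permittivity: float = 78.5

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.conductivity <= 0:
            raise ValueError("viscosity and conductivity must be positive")
        if self.rel_permittivity <= 0:
            raise ValueError("relative permittivity must be positive")


def zeta_potential(z: ZetaInputs) -> float:
    """Zeta potential in mV: zeta = (eta*lambda/(eps0*eps_r)) * (dE/dP)."""
    volts = (
        z.viscosity * z.conductivity / (VACUUM_PERMITTIVITY * z.rel_permittivity)
    ) * z.dE_dP
    return volts * 1e3


@dataclass(frozen=True)
class PlateReadings:
    """570/590 nm fluorescence readings of an alamarBlue viability plate."""

    experimental_rfu: float
    negative_control_rfu: float
    positive_control_rfu: float

    def __post_init__(self) -> None:
        if self.positive_control_rfu == self.negative_control_rfu:
            raise ValueError("positive and negative control RFUs must differ")


def alamar_reduction(r: PlateReadings) -> float:
    """Percent reduction of the alamarBlue reagent.

    100 * (experimental - negative) / (positive - negative); 0% at the
    negative control, 100% at the fully reduced positive control.
    """
    return 100.0 * (r.experimental_rfu - r.negative_control_rfu) / (
        r.positive_control_rfu - r.negative_control_rfu
    )


def relative_adhesion(reductions: dict, control_key: str) -> dict:
    """Per-substrate adhesion relative to a control substrate.

    Each percent-reduction value is divided by the control's; the control
    itself maps to exactly 1.0.
    """
    if control_key not in reductions:
        raise KeyError(f"control substrate {control_key!r} missing from readings")
    control = reductions[control_key]
    if control <= 0:
        raise ValueError("control reduction must be positive")
    out = {k: v / control for k, v in reductions.items()}
    out[control_key] = 1.0
    return out


@dataclass(frozen=True)
class FenceSchedule:
    """Electric-fence pulse schedule (1 mA on 8W1E wells, 6 mA on 8W10E)."""

    current_ma: float = 1.0
    carrier_frequency_hz: float = 40_000.0
    pulses_per_interval: int = 3
    interval_min: float = 5.0
    pulse_on_ms: float = 200.0
    pulse_off_ms: float = 200.0
    fence_off_time_h: float = 24.0

    def __post_init__(self) -> None:
        for name in ("current_ma", "carrier_frequency_hz", "interval_min",
                     "pulse_on_ms", "pulse_off_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pulses_per_interval < 1:
            raise ValueError("pulses_per_interval must be at least 1")

    @classmethod
    def for_array(cls, array_type: str, **kw) -> "FenceSchedule":
        current = {"8W1E": 1.0, "8W10E": 6.0}[array_type]
        return cls(current_ma=current, **kw)


def ef_voltage(well_resistance_ohm: float, fence: FenceSchedule) -> float:
    """Peak fence voltage V = I*R across a cell-free well, in volts."""
    if well_resistance_ohm <= 0:
        raise ValueError("well resistance must be positive")
    return fence.current_ma * 1e-3 * well_resistance_ohm


def radius_from_area(area_um2: float) -> float:
    """Equivalent cell radius rc = sqrt(Ac/pi) from a spread area in um^2."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return math.sqrt(area_um2 / math.pi)
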