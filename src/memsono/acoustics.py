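"""Acoustic bookkeeping: plane-wave intensity conversions and the
radiation-pressure bound.

For a travelling plane wave of peak pressure p in a medium of density
ρ₀ and sound speed c, the time-averaged intensity is I = p²/(2ρ₀c).
When the wave reflects from a pressure-release (air/water) interface
the interface moves with twice the incident particle velocity, so the
incident intensity in terms of the peak interface velocity u is
I = ρ₀c·u²/8. The maximal steady pressure radiation force can exert
(total reflection) is 2I/c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .params import MediumProperties


@dataclass
class AcousticStimulus:
    """Descriptor of one ultrasound stimulus. ``frequency_label`` is
    the nominal transducer frequency (metadata only — radiation force
    is, to first approximation, frequency independent)."""

    frequency_label: float
    I: Optional[float] = None        # intensity, W/m²
    p: Optional[float] = None        # peak acoustic pressure, Pa
    u_iface: Optional[float] = None  # peak interface velocity, m/s

    def __post_init__(self) -> None:
        given = [v for v in (self.I, self.p, self.u_iface) if v is not None]
        if len(given) != 1:
            raise ValueError("exactly one of I, p, u_iface must be given")
        if given[0] < 0:
            raise ValueError("acoustic quantities must be non-negative")


def intensity_from_pressure(p: float, med: MediumProperties) -> float:
    """Plane-wave intensity I = p²/(2ρ₀c) from hydrophone peak pressure (W/m²)."""
    if p < 0:
        raise ValueError("peak pressure must be non-negative")
    return p**2 / (2.0 * med.rho * med.c)


def pressure_from_intensity(I: float, med: MediumProperties) -> float:
    """Inverse of :func:`intensity_from_pressure`: p = √(2ρ₀cI) (Pa)."""
    if I < 0:
        raise ValueError("intensity must be non-negative")
    return (2.0 * med.rho * med.c * I) ** 0.5


def intensity_from_interface_velocity(u_iface: float, med: MediumProperties) -> float:
    """Incident intensity I = ρ₀c·u²/8 from the peak velocity of a
    totally reflecting air/water interface (W/m²)."""
    if u_iface < 0:
        raise ValueError("interface velocity must be non-negative")
    return med.rho * med.c * u_iface**2 / 8.0


def interface_velocity_from_intensity(I: float, med: MediumProperties) -> float:
    """Inverse of :func:`intensity_from_interface_velocity` (m/s)."""
    if I < 0:
        raise ValueError("intensity must be non-negative")
    return (8.0 * I / (med.rho * med.c)) ** 0.5


def max_radiation_pressure(I: float, c: float = 1500.0) -> float:
    """Upper bound 2I/c on the steady radiation-force pressure (N/m²)."""
    if I < 0:
        raise ValueError("intensity must be non-negative")
    if c <= 0:
        raise ValueError("sound speed must be positive")
    return 2.0 * I / c


def check_radiation_pressure(P_US: float, I: float, c: float = 1500.0) -> bool:
    """Warn if a configured radiation-force pressure exceeds the 2I/c
    bound; returns True when the value is physically admissible."""
    bound = max_radiation_pressure(I, c)
    if P_US > bound:
        warnings.warn(
            f"P_US = {P_US:.3g} N/m² exceeds the radiation-force bound "
            f"2I/c = {bound:.3g} N/m²", stacklevel=2
        )
        return False
    return True
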