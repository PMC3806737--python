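"""Physical parameter containers for the bilayer–solution system.

All quantities are SI internally. Conversions to the units customary at
the rig (µm, pF, pA, mN/m, W/cm²) happen only at the CLI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class BilayerParameters:
    """Geometry and material constants of a planar (black) lipid bilayer.

    Parameters
    ----------
    d : float
        Bilayer diameter (aperture diameter), m.
    gamma : float
        Interfacial tension, N/m. The restoring force of the
        interfacial standing wave.
    L0 : float
        Resting hydrophobic-core thickness, m. 4 nm is typical of
        solvent-containing bilayers.
    epsilon : float
        Relative dielectric constant of the hydrophobic core (~2).
    A0 : float, optional
        Resting (equilibrium) surface area, m². Populated by the
        equilibrium solve; never below the flat-disc area πd²/4.
    """

    d: float
    gamma: float
    L0: float = 4e-9
    epsilon: float = 2.0
    eps0: float = EPS0
    A0: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.d > 0, f"bilayer diameter must be positive, got {self.d}")
        _require(self.gamma > 0, f"interfacial tension must be positive, got {self.gamma}")
        _require(self.L0 > 0, f"resting thickness must be positive, got {self.L0}")
        _require(self.epsilon >= 1, f"relative dielectric constant must be >= 1, got {self.epsilon}")
        if self.A0 is not None:
            _require(
                self.A0 >= self.flat_area * (1 - 1e-12),
                "resting area cannot be below the flat-disc area",
            )

    @property
    def flat_area(self) -> float:
        """Area of the flat disc spanning the aperture, πd²/4 (m²)."""
        return np.pi * self.d**2 / 4

    @property
    def q(self) -> float:
        """Spatial frequency 2π/λ of the fundamental standing wave, 1/m.

        The clamped rim fixes the wavelength at twice the diameter,
        so q = π/d.
        """
        return np.pi / self.d


@dataclass
class MediumProperties:
    """Bulk properties of the aqueous solution surrounding the bilayer."""

    rho: float = 1000.0  # density, kg/m³
    eta: float = 1e-3    # dynamic viscosity, Pa·s
    c: float = 1500.0    # speed of sound, m/s

    def __post_init__(self) -> None:
        for name in ("rho", "eta", "c"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")


@dataclass
class PressureProgram:
    """Hydrostatic pressure plus a gated radiation-force drive.

    The total normal pressure on the bilayer is::

        P(t) = P0 + P_US * envelope(t - t_on)   for t_on <= t < t_off
        P(t) = P0                               otherwise

    ``envelope`` is a dimensionless intensity fraction in [0, 1]; the
    default (None) is an ideal step, matching the essentially
    step-like time course of radiation force at stimulus onset.
    """

    P0: float
    P_US: float
    t_on: float
    t_off: float
    envelope: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        _require(np.isfinite(self.P0), "P0 must be finite")
        _require(np.isfinite(self.P_US), "P_US must be finite")
        _require(self.t_off > self.t_on, "t_off must exceed t_on")

    def pressure(self, t) -> np.ndarray:
        """Total pressure P(t), N/m² (vectorized over t)."""
        t = np.asarray(t, dtype=float)
        gate = (t >= self.t_on) & (t < self.t_off)
        if self.envelope is None:
            env = gate.astype(float)
        else:
            env = np.where(gate, self.envelope(t - self.t_on), 0.0)
        return self.P0 + self.P_US * env


@dataclass
class SolverSettings:
    """Numerical settings for the method-of-lines displacement solver."""

    n_nodes: int = 201
    rtol: float = 1e-8
    atol: float = 1e-14
    dt_out: float = 1e-5  # 100 kHz, matching the recording sample rate

    def __post_init__(self) -> None:
        _require(self.n_nodes >= 51, "need at least 51 spatial nodes")
        _require(self.n_nodes % 2 == 1, "n_nodes must be odd so that x = 0 is a node")
        _require(self.rtol > 0 and self.atol > 0 and self.dt_out > 0,
                 "tolerances and output interval must be positive")
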