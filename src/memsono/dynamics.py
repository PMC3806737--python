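"""Interfacial-wave dynamics of a planar bilayer under radiation force.

The bilayer is treated as a fluid interface under tension, clamped at
the rim of its supporting aperture. A normal pressure — hydrostatic
offset plus the step-like radiation-force pressure during insonation —
drives a transverse standing wave whose pressure disturbance decays
evanescently into the bulk with spatial frequency q = π/d (wavelength
twice the diameter). Reducing the incompressible Navier–Stokes
equation under these assumptions gives, for the cross-sectional
displacement u(x, t) and velocity v = ∂u/∂t::

    ρ ∂v/∂t = q·(P(t) + 2γ ∂²u/∂x²) + 2η ∂²v/∂x²

with u(±d/2, t) = 0. The factor 2 on both the tension and viscous
terms comes from the axial symmetry of the profile (the two transverse
second derivatives are equal on the symmetry axis).

The equilibrium profile at pressure P is the solution of
2γ u″ = −P, a parabola with center depth P·d²/(16γ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, least_squares
from scipy.sparse.linalg import spsolve

from .params import BilayerParameters, MediumProperties, PressureProgram, SolverSettings


@dataclass
class DisplacementField:
    """Space–time displacement solution on the bilayer chord.

    Attributes
    ----------
    x : ndarray, shape (nx,)
        Node positions spanning [−d/2, +d/2], m.
    t : ndarray, shape (nt,)
        Sample times, s.
    u : ndarray, shape (nt, nx)
        Displacement, m, positive along the direction of ultrasound
        propagation. Zero at both rim nodes for every time.
    v : ndarray, shape (nt, nx)
        Velocity ∂u/∂t, m/s.
    q : float
        Spatial frequency of the fundamental standing wave, π/d (1/m).
    """

    x: np.ndarray
    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if self.u.shape != (self.t.size, self.x.size):
            raise ValueError("u must have shape (nt, nx)")
        if self.v.shape != self.u.shape:
            raise ValueError("v must have the same shape as u")

    @property
    def center_index(self) -> int:
        return int(np.argmin(np.abs(self.x)))

    def center_displacement(self) -> np.ndarray:
        """u(0, t) — where the displacement is greatest."""
        return self.u[:, self.center_index]


def equilibrium_profile(x: np.ndarray, P: float, d: float, gamma: float) -> np.ndarray:
    """Closed-form equilibrium parabola (P/4γ)(d²/4 − x²)."""
    return (P / (4.0 * gamma)) * (d**2 / 4.0 - np.asarray(x, dtype=float) ** 2)


def equilibrium_center_depth(P: float, d: float, gamma: float) -> float:
    """Center displacement of the equilibrium parabola, P·d²/(16γ)."""
    return P * d**2 / (16.0 * gamma)


def _grid(bp: BilayerParameters, n_nodes: int) -> np.ndarray:
    return np.linspace(-bp.d / 2.0, bp.d / 2.0, n_nodes)


def _laplacian(n_interior: int, h: float) -> sparse.csr_matrix:
    """Second-order central-difference Laplacian on the interior nodes
    with homogeneous Dirichlet boundaries."""
    main = np.full(n_interior, -2.0)
    off = np.ones(n_interior - 1)
    return sparse.diags([off, main, off], [-1, 0, 1], format="csr") / h**2


def solve_equilibrium(
    bp: BilayerParameters,
    P0: float,
    settings: Optional[SolverSettings] = None,
    set_A0: bool = True,
) -> DisplacementField:
    """Solve the equilibrium shape 2γ u″ = −P0 with a clamped rim.

    Solved as a linear boundary-value problem on the discretized chord
    (the closed-form parabola serves as an independent verification
    oracle in the test suite, not as the production path). When
    ``set_A0`` is true, ``bp.A0`` is populated with the axisymmetric
    surface area of the profile.

    Returns a single-time-slice :class:`DisplacementField` at t = 0.
    """
    if not np.isfinite(P0):
        raise ValueError("P0 must be finite")
    settings = settings or SolverSettings()
    x = _grid(bp, settings.n_nodes)
    h = x[1] - x[0]
    n_int = settings.n_nodes - 2
    L = _laplacian(n_int, h)
    rhs = np.full(n_int, -P0 / (2.0 * bp.gamma))
    u_int = spsolve((L).tocsc(), rhs)
    u = np.concatenate([[0.0], u_int, [0.0]])
    residual = np.max(np.abs(2.0 * bp.gamma * (L @ u_int) + P0))
    scale = max(abs(P0), 1.0)
    if not np.all(np.isfinite(u)) or residual > 1e-6 * scale:
        raise RuntimeError(
            f"equilibrium boundary-value solve did not converge on a "
            f"{settings.n_nodes}-node grid (residual {residual:.3e} N/m²)"
        )
    field = DisplacementField(x=x, t=np.array([0.0]), u=u[None, :],
                              v=np.zeros((1, x.size)), q=bp.q)
    if set_A0:
        from .electromechanics import compute_area

        bp.A0 = compute_area(field, 0)
    return field


def solve_dynamics(
    bp: BilayerParameters,
    med: MediumProperties,
    prog: PressureProgram,
    settings: Optional[SolverSettings] = None,
    t_end: Optional[float] = None,
) -> DisplacementField:
    """Integrate the displacement PDE by the method of lines.

    Space is discretized on a uniform grid with second-order central
    differences; the resulting stiff linear ODE system is integrated
    with an implicit BDF scheme using the exact sparse Jacobian.
    Integration restarts at the stimulus onset and offset so the
    step-change in forcing never straddles an integrator step.

    The initial condition is the equilibrium profile at ``prog.P0``
    with v(x, 0) = 0. The window runs from t = 0 to ``t_end``
    (default: one stimulus-duration past offset, covering both the On
    and the Off transient).
    """
    settings = settings or SolverSettings()
    eq = solve_equilibrium(bp, prog.P0, settings)
    x = eq.x
    h = x[1] - x[0]
    n_int = settings.n_nodes - 2
    L = _laplacian(n_int, h)
    q = bp.q

    if t_end is None:
        t_end = prog.t_off + (prog.t_off - prog.t_on)

    c_u = 2.0 * bp.gamma * q / med.rho
    c_v = 2.0 * med.eta / med.rho

    def rhs(t: float, z: np.ndarray) -> np.ndarray:
        u, v = z[:n_int], z[n_int:]
        dv = (q / med.rho) * prog.pressure(t) + c_u * (L @ u) + c_v * (L @ v)
        return np.concatenate([v, dv])

    I = sparse.identity(n_int, format="csr")
    J = sparse.bmat([[None, I], [c_u * L, c_v * L]], format="csr")

    z0 = np.concatenate([eq.u[0, 1:-1], np.zeros(n_int)])
    t_out = np.arange(0.0, t_end + 0.5 * settings.dt_out, settings.dt_out)

    # integrate segment-wise between forcing discontinuities
    breaks = [0.0] + [tb for tb in (prog.t_on, prog.t_off) if 0.0 < tb < t_end] + [t_end]
    u_rows = [z0[:n_int]]
    v_rows = [z0[n_int:]]
    t_acc = [0.0]
    z = z0
    tol = 1e-6 * settings.dt_out
    for ta, tb in zip(breaks[:-1], breaks[1:]):
        inside = t_out[(t_out > ta + tol) & (t_out < tb - tol)]
        grid_hits_tb = bool(np.any(np.abs(t_out - tb) <= tol))
        eval_pts = np.append(inside, tb)
        sol = solve_ivp(
            rhs, (ta, tb), z, method="BDF", jac=lambda t, z: J,
            t_eval=eval_pts, rtol=settings.rtol, atol=settings.atol,
        )
        if sol.status != 0 or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                f"displacement PDE integration failed on [{ta:g}, {tb:g}] s: "
                f"{sol.message}"
            )
        n_keep = inside.size + (1 if grid_hits_tb else 0)
        t_acc.extend(sol.t[:n_keep])
        u_rows.extend(sol.y[:n_int, :n_keep].T)
        v_rows.extend(sol.y[n_int:, :n_keep].T)
        z = sol.y[:, -1]

    t_arr = np.asarray(t_acc)
    nt = t_arr.size
    u = np.zeros((nt, x.size))
    v = np.zeros((nt, x.size))
    u[:, 1:-1] = np.asarray(u_rows)
    v[:, 1:-1] = np.asarray(v_rows)
    return DisplacementField(x=x, t=t_arr, u=u, v=v, q=q)


def modal_characteristics(
    bp: BilayerParameters, med: MediumProperties
) -> Tuple[float, float]:
    """Small-amplitude fundamental-mode frequency and damping rate.

    For the fundamental standing wave u ∝ cos(qx), q = π/d, the PDE
    reduces to a damped harmonic oscillator with natural angular
    frequency ω₀ = √(2γq³/ρ) and amplitude-decay rate α = ηq²/ρ.
    Returns ``(f0, alpha)`` with f0 = ω₀/2π in Hz and alpha in 1/s.
    Used as an analytic cross-check of the numerical solver.
    """
    q = bp.q
    omega0 = np.sqrt(2.0 * bp.gamma * q**3 / med.rho)
    alpha = med.eta * q**2 / med.rho
    return omega0 / (2.0 * np.pi), alpha


# ---------------------------------------------------------------------------
# Analytic forward map used for parameter calibration
# ---------------------------------------------------------------------------

def paraboloid_area(radius: float, depth: float) -> float:
    """Surface area of a paraboloid of revolution with rim ``radius``
    and center ``depth``: (πa/6h²)[(a² + 4h²)^{3/2} − a³]."""
    a, hh = radius, abs(depth)
    if hh == 0.0:
        return np.pi * a**2
    return (np.pi * a / (6.0 * hh**2)) * ((a**2 + 4.0 * hh**2) ** 1.5 - a**3)


def resting_capacitance_analytic(bp: BilayerParameters, P0: float) -> float:
    """Resting capacitance εε₀A0/L0 with A0 the closed-form
    paraboloid area of the equilibrium parabola (F)."""
    A0 = paraboloid_area(bp.d / 2.0, equilibrium_center_depth(P0, bp.d, bp.gamma))
    return bp.epsilon * bp.eps0 * A0 / bp.L0


def _forward_observables(
    d: float,
    gamma: float,
    P0: float,
    P_US: float,
    med: MediumProperties,
    bp_template: BilayerParameters,
    V: float,
) -> Tuple[float, float, float, float]:
    """Model (C, |amplitude|, f, alpha) for one bilayer diameter.

    Amplitude uses the single-mode approximation: the net capacitance
    change over the On step, converted to a damped-sine current
    amplitude at zero phase, a = |V·ΔC|·(α² + ω²)/ω.
    """
    bp = BilayerParameters(d=d, gamma=gamma, L0=bp_template.L0,
                           epsilon=bp_template.epsilon)
    a_rim = d / 2.0
    A0 = paraboloid_area(a_rim, equilibrium_center_depth(P0, d, gamma))
    A1 = paraboloid_area(a_rim, equilibrium_center_depth(P0 + P_US, d, gamma))
    C0 = bp.epsilon * bp.eps0 * A0 / bp.L0
    # constant-volume thinning makes C quadratic in area: C/C0 = (A/A0)²
    dC = C0 * ((A1 / A0) ** 2 - 1.0)
    f0, alpha = modal_characteristics(bp, med)
    omega = 2.0 * np.pi * f0
    amp = abs(V * dC) * (alpha**2 + omega**2) / omega
    return C0, amp, f0, alpha


@dataclass
class CalibrationResult:
    """Fitted parameters and diagnostics from :func:`calibrate_parameters`."""

    params: Dict[str, float]
    residuals: np.ndarray
    cost: float
    success: bool


def calibrate_parameters(
    observations: Sequence[Tuple[float, float, float, float]],
    free: Sequence[str] = ("gamma",),
    bp_template: Optional[BilayerParameters] = None,
    med: Optional[MediumProperties] = None,
    fixed: Optional[Dict[str, float]] = None,
    V: float = -0.2,
) -> CalibrationResult:
    """Least-squares fit of {γ, P0, P_US} to observed response curves.

    Each observation is a tuple ``(C, amplitude, f, alpha)`` — baseline
    capacitance in F, Off-response amplitude in A, frequency in Hz and
    damping in 1/s. For trial parameters the bilayer diameter behind
    each observed capacitance is recovered by inverting the modelled
    resting C(d), and log-residuals of (amplitude, f, alpha) against
    the model curves are minimized.
    """
    allowed = {"gamma", "P0", "P_US"}
    free = list(free)
    if not set(free) <= allowed:
        raise ValueError(f"free parameters must be among {sorted(allowed)}")
    if len(observations) < len(free):
        raise ValueError(
            f"under-determined calibration: {len(observations)} observation(s) "
            f"for {len(free)} free parameter(s)"
        )
    med = med or MediumProperties()
    bp_template = bp_template or BilayerParameters(d=120e-6, gamma=0.8e-3)
    defaults = {"gamma": 0.8e-3, "P0": -70.0, "P_US": 0.15}
    if fixed:
        defaults.update(fixed)

    obs = np.asarray(observations, dtype=float)
    if np.any(obs[:, 0] <= 0):
        raise ValueError("observed capacitances must be positive")

    def diameter_for_C(C_target, gamma, P0):
        def f(logd):
            d = np.exp(logd)
            bp = BilayerParameters(d=d, gamma=gamma, L0=bp_template.L0,
                                   epsilon=bp_template.epsilon)
            return np.log(resting_capacitance_analytic(bp, P0) / C_target)
        return np.exp(brentq(f, np.log(1e-6), np.log(5e-2), xtol=1e-12))

    def unpack(theta):
        p = dict(defaults)
        for name, val in zip(free, theta):
            p[name] = val
        return p

    def residual(theta):
        p = unpack(theta)
        if p["gamma"] <= 0:
            return np.full(3 * len(obs), 1e3)
        res = []
        for C_obs, a_obs, f_obs, al_obs in obs:
            try:
                d = diameter_for_C(C_obs, p["gamma"], p["P0"])
            except ValueError:
                return np.full(3 * len(obs), 1e3)
            _, a_m, f_m, al_m = _forward_observables(
                d, p["gamma"], p["P0"], p["P_US"], med, bp_template, V
            )
            res.extend([
                np.log(max(a_m, 1e-300) / max(abs(a_obs), 1e-300)),
                np.log(f_m / f_obs),
                np.log(al_m / al_obs),
            ])
        return np.asarray(res)

    x0 = np.array([defaults[name] for name in free])
    fit = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
    params = unpack(fit.x)
    return CalibrationResult(
        params={k: float(params[k]) for k in allowed},
        residuals=fit.fun,
        cost=float(fit.cost),
        success=bool(fit.success),
    )
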