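"""Quantification of On/Off capacitive-current transients.

The transient that follows stimulus onset or offset is a damped
sinusoid::

    y(t) = a · exp(−α t) · sin(2π f t + φ)

with t measured from the stimulus edge. This module fits that form to
recorded traces, converts fits to net capacitance changes (both by the
closed-form improper integral of the fit and by direct integration of
the trace), normalizes amplitudes across bilayers of different size by
a fitted capacitance power law, and converts capacitance to bilayer
perimeter through the equilibrium model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit
from scipy.signal import hilbert

from .dynamics import resting_capacitance_analytic
from .params import BilayerParameters, MediumProperties


@dataclass
class TraceRecord:
    """A sampled electrophysiology (or vibrometry) signal.

    ``meta`` carries, when known: holding potential ``V`` (volts),
    baseline capacitance ``C0`` (farads), stimulus ``t_on``/``t_off``
    (seconds) and the trial-averaging count ``n_avg``.
    """

    t: np.ndarray
    y: np.ndarray
    y_units: str = "pA"
    meta: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size != self.y.size:
            raise ValueError("t and y must have the same length")
        if self.t.size < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trace must be uniformly sampled")
        for key in ("t_on", "t_off"):
            if key in self.meta:
                tv = self.meta[key]
                if not (self.t[0] <= tv <= self.t[-1]):
                    raise ValueError(f"{key}={tv} lies outside the record")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def baseline_sd(self) -> float:
        """SD of the pre-stimulus baseline; falls back to a
        first-difference noise estimate when no baseline exists."""
        t_on = self.meta.get("t_on")
        if t_on is not None and np.sum(self.t < t_on) >= 8:
            return float(np.std(self.y[self.t < t_on]))
        return float(np.std(np.diff(self.y)) / np.sqrt(2.0))


@dataclass
class DampedSineFit:
    """Damped-sinusoid parameterization of one On or Off transient."""

    a: float        # amplitude, signal units
    f: float        # frequency, Hz
    alpha: float    # damping constant, 1/s
    phi: float      # phase, rad, wrapped to (−π, π]
    stderr: Dict[str, float]
    window: str
    oscillation: bool = True
    residual_rms: float = 0.0

    def __call__(self, tau) -> np.ndarray:
        """Evaluate the fitted model at times ``tau`` from the edge."""
        tau = np.asarray(tau, dtype=float)
        return damped_sine(tau, self.a, self.f, self.alpha, self.phi)


def damped_sine(tau, a, f, alpha, phi):
    return a * np.exp(-alpha * np.asarray(tau)) * np.sin(2.0 * np.pi * f * np.asarray(tau) + phi)


def _wrap_phase(phi: float) -> float:
    phi = (phi + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if phi == -np.pi else phi


def _initial_guess(tau: np.ndarray, y: np.ndarray, noise_sd: float):
    """Deterministic initialization: f from the dominant FFT peak,
    α from a log-linear fit to the analytic-signal envelope, a and φ
    from the analytic signal at the edge."""
    dt = tau[1] - tau[0]
    spec = np.abs(np.fft.rfft(y - y.mean()))
    freqs = np.fft.rfftfreq(y.size, dt)
    k = int(np.argmax(spec[1:])) + 1
    f0 = max(freqs[k], 1.0 / (tau[-1] - tau[0]))

    analytic = hilbert(y)
    env = np.abs(analytic)
    usable = env > max(2.0 * noise_sd, 1e-3 * env.max())
    idx = np.flatnonzero(usable)
    if idx.size >= 4:
        sl, ic = np.polyfit(tau[idx], np.log(env[idx]), 1)
        alpha0 = max(-sl, 1e-6)
        a0 = np.exp(ic)
    else:
        alpha0 = 1.0 / max(tau[-1] - tau[0], dt)
        a0 = env.max()
    # sin(θ) = cos(θ − π/2): analytic-signal angle at the edge is φ − π/2
    phi0 = _wrap_phase(float(np.angle(analytic[0])) + np.pi / 2.0)
    return a0, f0, alpha0, phi0


def fit_damped_sine(
    trace: TraceRecord,
    window: str = "off",
    min_periods: float = 2.0,
) -> DampedSineFit:
    """Nonlinear least-squares fit of a damped sinusoid to one transient.

    ``window`` selects the segment following stimulus onset ("on",
    truncated at offset) or offset ("off"). The fit window extends
    from the stimulus edge to where the envelope estimate falls below
    twice the baseline noise SD, but never below ``min_periods``
    oscillation periods of the initial frequency estimate. Parameter
    SDs come from the fit covariance. When the fitted amplitude is
    indistinguishable from noise (|a| ≤ 2 × baseline SD) the result is
    flagged ``oscillation=False`` — the behaviour of stiff, strongly
    damped membranes such as those formed from cholesterol.
    """
    if window not in ("on", "off"):
        raise ValueError("window must be 'on' or 'off'")
    edge_key = "t_on" if window == "on" else "t_off"
    if edge_key not in trace.meta:
        raise ValueError(f"trace metadata lacks {edge_key}")
    edge = trace.meta[edge_key]

    sel = trace.t >= edge
    if window == "on" and "t_off" in trace.meta:
        sel &= trace.t < trace.meta["t_off"]
    tau = trace.t[sel] - edge
    y = trace.y[sel].astype(float)

    # remove the pre-stimulus baseline current
    t_on = trace.meta.get("t_on")
    if t_on is not None and np.any(trace.t < t_on):
        y = y - np.mean(trace.y[trace.t < t_on])

    noise_sd = trace.baseline_sd()
    if np.max(np.abs(y)) <= 2.0 * noise_sd:
        return DampedSineFit(a=0.0, f=np.nan, alpha=np.nan, phi=np.nan,
                             stderr={}, window=window, oscillation=False,
                             residual_rms=float(np.sqrt(np.mean(y**2))))

    a0, f0, alpha0, phi0 = _initial_guess(tau, y, noise_sd)

    # truncate where the envelope estimate drops below 2× noise
    n_min = int(np.ceil(min_periods / max(f0, 1.0) * trace.sample_rate))
    if noise_sd > 0 and alpha0 > 0 and a0 > 2.0 * noise_sd:
        t_cut = np.log(a0 / (2.0 * noise_sd)) / alpha0
        n_cut = int(np.searchsorted(tau, t_cut))
        n_keep = min(tau.size, max(n_cut, n_min))
    else:
        n_keep = tau.size
    if tau.size < n_min:
        raise RuntimeError(
            f"fit window holds fewer than {min_periods} periods of the "
            f"initial frequency estimate ({f0:.0f} Hz)"
        )
    tau_fit, y_fit = tau[:n_keep], y[:n_keep]

    try:
        popt, pcov = curve_fit(
            damped_sine, tau_fit, y_fit, p0=[a0, f0, alpha0, phi0], maxfev=20000
        )
    except RuntimeError as err:
        raise RuntimeError(
            "damped-sine fit did not converge from the initial estimates "
            f"a={a0:.3g}, f={f0:.3g} Hz, alpha={alpha0:.3g} 1/s, "
            f"phi={phi0:.3g} rad"
        ) from err

    a, f, alpha, phi = popt
    # canonicalize sign/branch ambiguities of the parameterization:
    # f > 0, and φ folded into (−π/2, π/2] with the sign carried by a
    # (the convention of the published fit tables)
    if f < 0:
        f, a, phi = -f, -a, -phi
    if alpha < 0:
        raise RuntimeError("fit converged to a growing oscillation (alpha < 0)")
    phi = _wrap_phase(phi)
    if phi > np.pi / 2:
        phi, a = phi - np.pi, -a
    elif phi <= -np.pi / 2:
        phi, a = phi + np.pi, -a

    sd = np.sqrt(np.abs(np.diag(pcov)))
    resid = y_fit - damped_sine(tau_fit, a, f, alpha, phi)
    oscillation = bool(abs(a) > 2.0 * noise_sd)
    return DampedSineFit(
        a=float(a), f=float(f), alpha=float(alpha), phi=float(phi),
        stderr={"a": sd[0], "f": sd[1], "alpha": sd[2], "phi": sd[3]},
        window=window, oscillation=oscillation,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def net_dC_from_fit(fit: DampedSineFit, V: float) -> float:
    """Net capacitance change from the closed-form improper integral of
    the fitted transient divided by the holding potential::

        ΔC = (a/V) · (ω cosφ + α sinφ) / (α² + ω²),  ω = 2πf
    """
    if V == 0:
        raise ValueError("holding potential must be nonzero")
    if not fit.oscillation:
        return 0.0
    omega = 2.0 * np.pi * fit.f
    return (fit.a / V) * (omega * np.cos(fit.phi) + fit.alpha * np.sin(fit.phi)) / (
        fit.alpha**2 + omega**2
    )


def net_dC_direct(
    trace: TraceRecord,
    V: Optional[float] = None,
    settle_window: float = 1e-3,
) -> float:
    """Net capacitance change by direct integration of the current.

    The baseline current (mean over the pre-stimulus segment) is
    subtracted, the trace is cumulatively integrated and divided by
    the holding potential to give C(t) − C0, and the reported change
    is the mean over the final ``settle_window`` (1 ms) of the
    stimulus. Unlike the fit-based estimator this also picks up any
    slow, non-oscillatory capacitance drift present in the trace.
    """
    V = V if V is not None else trace.meta.get("V")
    if V is None or V == 0:
        raise ValueError("holding potential must be provided and nonzero")
    t_on = trace.meta.get("t_on")
    t_off = trace.meta.get("t_off")
    if t_on is None or t_off is None:
        raise ValueError("trace metadata must include t_on and t_off")
    pre = trace.t < t_on
    if not np.any(pre):
        raise ValueError("trace has no pre-stimulus baseline segment")
    baseline = float(np.mean(trace.y[pre]))
    dC = cumulative_trapezoid(trace.y - baseline, trace.t, initial=0.0) / V
    sel = (trace.t >= t_off - settle_window) & (trace.t <= t_off)
    return float(np.mean(dC[sel]))


@dataclass
class PowerLawFit:
    """Amplitude–capacitance normalization law F_C(C) = k·C^β."""

    k: float
    beta: float
    k_sd: float
    beta_sd: float
    C_range: Tuple[float, float]
    saturated: bool = False

    def __call__(self, C) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        if np.any(C <= 0):
            raise ValueError("capacitance must be positive")
        return self.k * C**self.beta


def fit_amplitude_capacitance_law(
    points: Sequence[Tuple[float, float]]
) -> PowerLawFit:
    """Fit the normalization function F_C(C) = k·C^β by least squares
    in log space to (capacitance, amplitude-magnitude) pairs.

    With exactly two points the power law interpolates them exactly and
    the result is flagged ``saturated`` (no degrees of freedom left to
    validate the form).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (C, amplitude) points")
    C, a = pts[:, 0], np.abs(pts[:, 1])
    if np.any(C <= 0):
        raise ValueError("capacitances must be positive")
    if np.any(a <= 0):
        raise ValueError("amplitudes must be nonzero after taking magnitudes")
    logC, loga = np.log(C), np.log(a)
    if pts.shape[0] == 2:
        beta = (loga[1] - loga[0]) / (logC[1] - logC[0])
        k = np.exp(loga[0] - beta * logC[0])
        return PowerLawFit(k=float(k), beta=float(beta), k_sd=np.nan,
                           beta_sd=np.nan, C_range=(C.min(), C.max()),
                           saturated=True)
    coeffs, cov = np.polyfit(logC, loga, 1, cov=True)
    beta, logk = coeffs
    sd = np.sqrt(np.diag(cov))
    return PowerLawFit(
        k=float(np.exp(logk)), beta=float(beta),
        k_sd=float(np.exp(logk) * sd[1]), beta_sd=float(sd[0]),
        C_range=(float(C.min()), float(C.max())),
    )


def normalize_amplitude(a: float, C: float, C0: float, F_C: PowerLawFit) -> float:
    """Size-normalized amplitude a_n = a·F_C(C0)/F_C(C).

    Removes the dependence of response amplitude on bilayer size so
    responses recorded at different capacitances are comparable;
    a_n = a when C = C0.
    """
    if C <= 0 or C0 <= 0:
        raise ValueError("capacitances must be positive")
    return float(a * F_C(C0) / F_C(C))


@dataclass
class PerimeterModel:
    """Power-law map from capacitance to bilayer perimeter, built from
    the equilibrium model over a range of diameters."""

    law: PowerLawFit

    def __call__(self, C) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        lo, hi = self.law.C_range
        if np.any((C < lo) | (C > hi)):
            warnings.warn(
                "capacitance outside the fitted model range; "
                "perimeter is extrapolated", stacklevel=2
            )
        return self.law(C)


def build_perimeter_model(
    gamma: float,
    P0: float,
    L0: float = 4e-9,
    epsilon: float = 2.0,
    d_range: Tuple[float, float] = (100e-6, 1e-3),
    n_points: int = 40,
) -> PerimeterModel:
    """Fit a power law to the modelled capacitance–perimeter relation
    at fixed (γ, P0) over a range of bilayer diameters.

    The default range spans the aperture diameters used in planar
    bilayer rigs (~0.1–1 mm); the power law is a local approximation,
    so widening the range degrades it.
    """
    diam = np.geomspace(d_range[0], d_range[1], n_points)
    C = np.array([
        resting_capacitance_analytic(
            BilayerParameters(d=d, gamma=gamma, L0=L0, epsilon=epsilon), P0
        )
        for d in diam
    ])
    perim = np.pi * diam
    law = fit_amplitude_capacitance_law(list(zip(C, perim)))
    return PerimeterModel(law=law)


def perimeter_from_capacitance(
    C: float,
    gamma: float = 0.8e-3,
    P0: float = -70.0,
    **kwargs,
) -> float:
    """Bilayer perimeter (m) estimated from capacitance through the
    equilibrium model; monotone increasing in C."""
    model = build_perimeter_model(gamma=gamma, P0=P0, **kwargs)
    return float(model(C))
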