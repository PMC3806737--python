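"""Linear-system view of the bilayer response to ultrasound.

Because the displacement PDE is linear in (u, v, P), the current in
response to a standard (step-like) stimulus is the step response of a
linear time-invariant system. Differentiating the step response gives
the impulse response, whose causal convolution with any dimensionless
intensity envelope predicts the response to modulated stimuli — e.g.
quadratically ramped pulses — without re-solving the PDE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .waveform import TraceRecord


@dataclass
class ImpulseResponse:
    """Impulse response on the step trace's uniform time grid.

    ``h`` has units of (signal units)/s; its time integral equals the
    step response's final value.
    """

    t: np.ndarray
    h: np.ndarray
    source: str = "measured"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.t.size != self.h.size:
            raise ValueError("t and h must have the same length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def step_to_impulse(step_trace: TraceRecord, source: str = "measured") -> ImpulseResponse:
    """Impulse response as the discrete time-derivative of a step response.

    ``step_trace`` must be an On-response segment starting at the
    stimulus edge with the pre-edge baseline already removed. The
    derivative is the causal (backward) difference with
    h[0] = y[0]/Δt, the exact discrete inverse of causal convolution
    with a unit step: a discrete Heaviside step maps to a
    single-sample impulse of height 1/Δt, and convolving ``h`` back
    with a unit step reproduces the input step response exactly.
    """
    dt = np.diff(step_trace.t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("step response must be uniformly sampled")
    h = np.empty_like(step_trace.y, dtype=float)
    h[0] = step_trace.y[0] / dt[0]
    h[1:] = np.diff(step_trace.y) / dt[0]
    return ImpulseResponse(t=step_trace.t - step_trace.t[0], h=h, source=source)


def predict_response(
    h: ImpulseResponse,
    envelope: np.ndarray,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Causal convolution of the impulse response with a dimensionless
    intensity envelope (values in [0, 1], sampled on h's grid).

    Radiation pressure is taken proportional to instantaneous
    intensity, so the envelope multiplies the drive directly. The
    output has the envelope's length. Optional seeded Gaussian noise
    emulates adding baseline-level recording noise to a prediction.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.ndim != 1:
        raise ValueError("envelope must be one-dimensional")
    if np.any(envelope < -1e-12) or np.any(envelope > 1.0 + 1e-12):
        raise ValueError("envelope values must lie in [0, 1]")
    y = np.convolve(envelope, h.h)[: envelope.size] * h.dt
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return y


def quadratic_ramp_envelope(
    t: np.ndarray, ramp: float, t_on: float = 0.0, t_off: Optional[float] = None
) -> np.ndarray:
    """Quadratically rising (and optionally falling) intensity envelope.

    Rises as ((t − t_on)/ramp)² to 1 over ``ramp`` seconds; if
    ``t_off`` is given, falls back to 0 quadratically after it.
    """
    t = np.asarray(t, dtype=float)
    env = np.zeros_like(t)
    rise = (t >= t_on) & (t < t_on + ramp)
    env[rise] = ((t[rise] - t_on) / ramp) ** 2
    env[t >= t_on + ramp] = 1.0
    if t_off is not None:
        fall = (t >= t_off) & (t < t_off + ramp)
        env[fall] = (1.0 - (t[fall] - t_off) / ramp) ** 2
        env[t >= t_off + ramp] = 0.0
    return env
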