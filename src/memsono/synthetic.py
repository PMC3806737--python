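"""Synthetic voltage-clamp traces with the statistical structure of the
recordings.

Two generators are provided. ``generate_onoff_trace`` composes an
On/Off pair of damped sinusoids — the Off transient opposite in
polarity but otherwise mirroring the On transient — with seeded
Gaussian baseline noise and an optional hardware-style low-pass
filter (100-kHz sampling, 10-kHz cutoff by default, as at the rig).
``generate_model_trace`` runs the full physical pipeline instead:
equilibrium → displacement PDE → area → capacitance → capacitive
current, then adds noise. Presets matching the published example
recordings are available through ``make_fixture_suite``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import bessel, lfilter

from .dynamics import solve_dynamics
from .electromechanics import VoltageClampConfig, electrical_series
from .params import BilayerParameters, MediumProperties, PressureProgram, SolverSettings
from .waveform import TraceRecord, damped_sine


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic On/Off capacitive-current trace.

    ``on_params``/``off_params`` are (a, f, alpha, phi) damped-sine
    parameter tuples in (signal units, Hz, 1/s, rad). If
    ``off_params`` is None the Off transient is the polarity-flipped
    On transient. ``slow_component`` is an optional
    (amplitude, time-constant) exponential drift during the stimulus,
    emulating slow lipid exchange with the solvent torus.
    """

    on_params: Tuple[float, float, float, float]
    off_params: Optional[Tuple[float, float, float, float]] = None
    t_on: float = 5e-3
    t_off: float = 15e-3
    duration: float = 30e-3
    sample_rate: float = 100e3
    noise_sd: float = 0.0
    lowpass_hz: Optional[float] = 10e3
    filter_order: int = 4
    slow_component: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")
        if self.t_off >= self.duration:
            raise ValueError("stimulus must end before the record does")
        if self.lowpass_hz is not None and self.sample_rate <= 2 * self.lowpass_hz:
            raise ValueError("sample_rate must exceed twice the low-pass cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def lowpass_filter(y: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    """Causal low-pass Bessel filter, the linear-phase-like type found
    in patch-clamp hardware."""
    b, a = bessel(order, cutoff / (fs / 2.0), btype="low")
    return lfilter(b, a, y)


def filtered_noise_sd_factor(cutoff: float, fs: float, order: int = 4) -> float:
    """Analytic SD ratio of white Gaussian noise after the low-pass
    Bessel filter: the root sum of squares of the filter's impulse
    response."""
    n = int(20 * fs / cutoff)
    impulse = np.zeros(n)
    impulse[0] = 1.0
    h = lowpass_filter(impulse, cutoff, fs, order)
    return float(np.sqrt(np.sum(h**2)))


def generate_onoff_trace(spec: SyntheticSpec) -> TraceRecord:
    """Noisy On/Off damped-sinusoid trace, reproducible per seed."""
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    y = np.zeros(n)

    on = t >= spec.t_on
    y[on] += damped_sine(t[on] - spec.t_on, *spec.on_params)
    off_params = spec.off_params
    if off_params is None:
        a, f, al, ph = spec.on_params
        off_params = (-a, f, al, ph)
    off = t >= spec.t_off
    y[off] += damped_sine(t[off] - spec.t_off, *off_params)

    if spec.slow_component is not None:
        amp, tau = spec.slow_component
        during = (t >= spec.t_on) & (t < spec.t_off)
        y[during] += amp * (1.0 - np.exp(-(t[during] - spec.t_on) / tau))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.lowpass_hz is not None:
        y = lowpass_filter(y, spec.lowpass_hz, spec.sample_rate, spec.filter_order)
    return TraceRecord(
        t=t, y=y, y_units="pA",
        meta={"t_on": spec.t_on, "t_off": spec.t_off, "seed": spec.seed,
              "noise_sd": spec.noise_sd},
    )


def generate_model_trace(
    bp: BilayerParameters,
    med: MediumProperties,
    prog: PressureProgram,
    cfg: VoltageClampConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    settings: Optional[SolverSettings] = None,
    lowpass_hz: Optional[float] = None,
    t_end: Optional[float] = None,
) -> TraceRecord:
    """End-to-end simulated capacitive-current trace in pA.

    Runs the displacement PDE and the electromechanical pipeline, adds
    seeded Gaussian noise, and records the generating parameters in
    the trace metadata.
    """
    settings = settings or SolverSettings()
    field_ = solve_dynamics(bp, med, prog, settings, t_end=t_end)
    series = electrical_series(field_, bp, cfg)
    y = series.I_C * 1e12  # A -> pA
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    if lowpass_hz is not None:
        y = lowpass_filter(y, lowpass_hz, 1.0 / settings.dt_out)
    return TraceRecord(
        t=series.t, y=y, y_units="pA",
        meta={"t_on": prog.t_on, "t_off": prog.t_off, "V": cfg.V0,
              "C0": float(series.C[0]), "seed": seed, "noise_sd": noise_sd,
              "d": bp.d, "gamma": bp.gamma, "P0": prog.P0, "P_US": prog.P_US},
    )


#: Damped-sine presets (a pA, f Hz, alpha 1/s, phi rad) drawn from the
#: published example recordings, keyed by the figure-like scenario they
#: emulate, with the baseline capacitance scale of each recording.
TRACE_PRESETS: Dict[str, Dict] = {
    "fig1": {  # 170-pF phospholipid bilayer, 1 MHz
        "on_params": (800.0, 900.0, 700.0, -0.21),
        "off_params": (-790.0, 950.0, 720.0, -0.25),
        "C0_pF": 170.0, "noise_sd": 50.0,
    },
    "fig4": {  # squalene (solvent-free-like) bilayer: smaller, slower
        "on_params": (110.0, 400.0, 340.0, 0.19),
        "off_params": (-110.0, 400.0, 340.0, 0.19),
        "C0_pF": 500.0, "noise_sd": 20.0,
    },
    "fig7a-small": {  # 30-pF bilayer: fast, strongly damped
        "on_params": (290.0, 2680.0, 1370.0, -0.68),
        "off_params": (-290.0, 2680.0, 1370.0, -0.68),
        "C0_pF": 30.0, "noise_sd": 30.0,
    },
    "fig7a-large": {  # 1300-pF bilayer: slow, lightly damped — longer
        # record so the Off window holds several 150-Hz periods
        "on_params": (1570.0, 150.0, 270.0, 0.06),
        "off_params": (-1570.0, 150.0, 270.0, 0.06),
        "C0_pF": 1300.0, "noise_sd": 50.0,
        "timing": {"t_on": 5e-3, "t_off": 45e-3, "duration": 85e-3},
    },
}

#: Full model configuration of the 100-pF reference simulation.
MODEL_PRESET: Dict[str, float] = {
    "d": 120e-6, "gamma": 0.8e-3, "L0": 4e-9, "epsilon": 2.0,
    "rho": 1000.0, "eta": 1e-3, "c": 1500.0,
    "P0": -70.0, "P_US": 0.15, "t_on": 5e-3, "t_off": 15e-3, "V0": -0.2,
}


def trace_from_preset(name: str, seed: int = 0, **overrides) -> TraceRecord:
    """Generate a trace from a named preset ('fig1', 'fig4',
    'fig7a-small', 'fig7a-large')."""
    if name not in TRACE_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(TRACE_PRESETS)}")
    preset = TRACE_PRESETS[name]
    kwargs = dict(preset.get("timing", {}))
    kwargs.update(overrides)
    spec = SyntheticSpec(
        on_params=preset["on_params"], off_params=preset["off_params"],
        noise_sd=preset["noise_sd"], seed=seed, **kwargs,
    )
    trace = generate_onoff_trace(spec)
    trace.meta["C0"] = preset["C0_pF"] * 1e-12
    trace.meta["V"] = -0.2
    trace.meta["preset"] = name
    return trace


def make_fixture_suite(out_dir, seed: int = 0) -> Dict[str, dict]:
    """Write the full preset suite plus a manifest of seeds and truth
    parameters to ``out_dir``; returns the manifest. Regenerating with
    the same seed reproduces the files bit-identically."""
    from .io import write_trace

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, dict] = {}
    for name in TRACE_PRESETS:
        trace = trace_from_preset(name, seed=seed)
        path = out / f"{name}.txt"
        write_trace(trace, path)
        manifest[name] = {
            "file": path.name, "seed": seed,
            "truth": {
                "on_params": list(TRACE_PRESETS[name]["on_params"]),
                "off_params": list(TRACE_PRESETS[name]["off_params"]),
                "C0_pF": TRACE_PRESETS[name]["C0_pF"],
                "noise_sd": TRACE_PRESETS[name]["noise_sd"],
            },
        }
    manifest["model"] = {"file": None, "config": dict(MODEL_PRESET), "seed": seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
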