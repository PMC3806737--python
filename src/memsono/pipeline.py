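"""End-to-end workflow: equilibrium → dynamics → electromechanics → fits.

This reproduces, from a single config, the reference-simulation
workflow: solve the resting shape, integrate the displacement PDE
through an On/Off stimulus, derive the electrical time series, fit the
On and Off current transients, and summarize displacement/area/
capacitance changes. Deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .dynamics import DisplacementField, solve_dynamics, solve_equilibrium
from .electromechanics import ElectricalTimeSeries, VoltageClampConfig, electrical_series
from .io import RunManifest, load_config, write_trace
from .params import BilayerParameters, MediumProperties, PressureProgram, SolverSettings
from .waveform import DampedSineFit, TraceRecord, fit_damped_sine


def objects_from_config(cfg: Dict[str, float]):
    """Materialize parameter objects from a validated config dict."""
    bp = BilayerParameters(d=cfg["d"], gamma=cfg["gamma"], L0=cfg["L0"],
                           epsilon=cfg["epsilon"])
    med = MediumProperties(rho=cfg["rho"], eta=cfg["eta"], c=cfg["c"])
    prog = PressureProgram(P0=cfg["P0"], P_US=cfg["P_US"],
                           t_on=cfg["t_on"], t_off=cfg["t_off"])
    settings = SolverSettings(n_nodes=int(cfg["n_nodes"]), rtol=cfg["rtol"],
                              dt_out=cfg["dt_out"])
    return bp, med, prog, settings


@dataclass
class PipelineResult:
    """Bundle of everything one simulation run produces."""

    config: Dict[str, float]
    field: DisplacementField
    series: ElectricalTimeSeries
    trace: TraceRecord
    on_fit: Optional[DampedSineFit]
    off_fit: Optional[DampedSineFit]
    summary: Dict[str, float]
    manifest: RunManifest


def run_pipeline(config, out_dir=None) -> PipelineResult:
    """Run the full simulation + analysis workflow for one config.

    ``config`` is a path to a YAML/JSON file or a dict. When
    ``out_dir`` is given, the current trace and a JSON manifest with
    file digests are written there.
    """
    cfg = load_config(config)
    bp, med, prog, settings = objects_from_config(cfg)

    eq = solve_equilibrium(bp, prog.P0, settings)
    field = solve_dynamics(bp, med, prog, settings)
    vc = VoltageClampConfig(V0=cfg["V0"], mode="vclamp")
    series = electrical_series(field, bp, vc)

    trace = TraceRecord(
        t=series.t, y=series.I_C * 1e12, y_units="pA",
        meta={"t_on": prog.t_on, "t_off": prog.t_off, "V": cfg["V0"],
              "C0": float(series.C[0]), "seed": cfg["seed"]},
    )
    on_fit = fit_damped_sine(trace, window="on")
    off_fit = fit_damped_sine(trace, window="off")

    uc = field.center_displacement()
    u_rest = uc[0]
    on_mask = (field.t >= prog.t_on) & (field.t < prog.t_off)
    du = uc - u_rest
    A_rest = series.A[0]
    dA_rel = 100.0 * np.abs(series.A - A_rest) / A_rest
    i_end = np.flatnonzero(on_mask)[-1]
    summary = {
        "C0_pF": float(series.C[0] * 1e12),
        "u_center_rest_um": float(u_rest * 1e6),
        "du_center_steady_um": float(du[i_end] * 1e6),
        "du_center_peak_um": float(np.max(np.abs(du[on_mask])) * 1e6),
        "dA_steady_pct": float(dA_rel[i_end]),
        "dA_peak_pct": float(np.max(dA_rel[on_mask])),
    }

    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trace_path = out / "current_trace.txt"
        write_trace(trace, trace_path)
        manifest.add_file("current_trace", trace_path)
        manifest.write(out / "manifest.json")

    return PipelineResult(config=cfg, field=field, series=series, trace=trace,
                          on_fit=on_fit, off_fit=off_fit, summary=summary,
                          manifest=manifest)
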