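"""Trace/field readers and writers, config parsing, and run manifests.

Trace dialect: plain delimited text, two columns (time_s, value),
preceded by commented ``# key = value`` metadata lines that must
include a ``units`` entry. The writer emits the same dialect it
reads; write∘read is the identity to 1e-12 relative. CRLF and LF line
endings are both accepted.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .dynamics import DisplacementField
from .waveform import TraceRecord


class TraceFormatError(ValueError):
    """Raised for malformed trace files, naming the offending line."""


def write_trace(trace: TraceRecord, path) -> None:
    path = Path(path)
    lines = [f"# units = {trace.y_units}"]
    for key in sorted(trace.meta):
        val = trace.meta[key]
        if isinstance(val, float):
            val = f"{val:.12g}"
        lines.append(f"# {key} = {val}")
    lines.append("time_s\tvalue")
    for t, y in zip(trace.t, trace.y):
        lines.append(f"{t:.12g}\t{y:.12g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> TraceRecord:
    path = Path(path)
    meta: Dict[str, float] = {}
    units: Optional[str] = None
    rows_t, rows_y = [], []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceFormatError(
                        f"{path.name}:{lineno}: malformed metadata line {line!r}"
                    )
                key, _, val = (s.strip() for s in body.partition("="))
                if key == "units":
                    units = val
                else:
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceFormatError(
                    f"{path.name}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                rows_t.append(float(parts[0]))
                rows_y.append(float(parts[1]))
            except ValueError as err:
                raise TraceFormatError(
                    f"{path.name}:{lineno}: non-numeric sample {line!r}"
                ) from err
    if units is None:
        raise TraceFormatError(f"{path.name}: missing '# units = ...' metadata line")
    if len(rows_t) < 2:
        raise TraceFormatError(f"{path.name}: fewer than two data rows")
    return TraceRecord(t=np.asarray(rows_t), y=np.asarray(rows_y),
                       y_units=units, meta=meta)


def write_field(field_: DisplacementField, path, fmt: str = "text") -> None:
    """Write a displacement field in long format (t, x, u, v), either
    as delimited text or HDF5 (for large runs)."""
    path = Path(path)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=field_.t)
            fh.create_dataset("x", data=field_.x)
            fh.create_dataset("u", data=field_.u)
            fh.create_dataset("v", data=field_.v)
            fh.attrs["q"] = field_.q
        return
    with open(path, "w") as fh:
        fh.write(f"# q = {field_.q:.12g}\n")
        fh.write("t_s\tx_m\tu_m\tv_m_per_s\n")
        for i, t in enumerate(field_.t):
            for j, x in enumerate(field_.x):
                fh.write(f"{t:.12g}\t{x:.12g}\t{field_.u[i, j]:.12g}\t"
                         f"{field_.v[i, j]:.12g}\n")


def read_field(path) -> DisplacementField:
    """Read a displacement field written by :func:`write_field`
    (text long format or HDF5, chosen by content)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            return DisplacementField(
                x=fh["x"][:], t=fh["t"][:], u=fh["u"][:], v=fh["v"][:],
                q=float(fh.attrs["q"]),
            )
    q = None
    data = []
    with open(path, "r", newline=None) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("t_s"):
                continue
            if line.startswith("#"):
                key, _, val = (s.strip() for s in line[1:].partition("="))
                if key == "q":
                    q = float(val)
                continue
            data.append([float(s) for s in line.split()])
    arr = np.asarray(data)
    if q is None or arr.ndim != 2 or arr.shape[1] != 4:
        raise TraceFormatError(f"{path.name}: not a long-format field file")
    t = np.unique(arr[:, 0])
    x = np.unique(arr[:, 1])
    u = arr[:, 2].reshape(t.size, x.size)
    v = arr[:, 3].reshape(t.size, x.size)
    return DisplacementField(x=x, t=t, u=u, v=v, q=q)


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

#: Defaults mirroring the standard experimental conditions: water at
#: room temperature, a solvent-containing bilayer, a 10-ms stimulus.
DEFAULT_CONFIG: Dict[str, float] = {
    "rho": 1000.0, "eta": 1e-3, "c": 1500.0,
    "gamma": 0.8e-3, "P0": -70.0, "P_US": 0.15,
    "d": 120e-6, "L0": 4e-9, "epsilon": 2.0,
    "t_on": 5e-3, "t_off": 15e-3,
    "n_nodes": 201, "rtol": 1e-8, "dt_out": 1e-5,
    "V0": -0.2, "seed": 0,
}

REQUIRED_KEYS = ("d", "gamma", "P0", "P_US", "t_on", "t_off")


def load_config(path_or_dict) -> Dict[str, float]:
    """Load a YAML/JSON config, fill defaults, and validate the schema.

    A missing required key raises ``KeyError`` naming the key; an
    unknown key raises ``ValueError`` naming it.
    """
    if isinstance(path_or_dict, dict):
        user = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in REQUIRED_KEYS:
        if key not in user:
            raise KeyError(f"config is missing required key {key!r}")
    cfg = dict(DEFAULT_CONFIG)
    # YAML 1.1 reads scientific notation without a decimal point
    # ("120e-6") as a string; coerce every value to a number
    for key, val in user.items():
        if isinstance(val, str):
            try:
                val = float(val)
            except ValueError as err:
                raise ValueError(f"config key {key!r}: non-numeric value "
                                 f"{val!r}") from err
        cfg[key] = val
    return cfg


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record tying a run's outputs to its config and seed."""

    config: Dict[str, float]
    version: str = field(default_factory=lambda: __version__)
    seed: int = 0
    digests: Dict[str, str] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_file(self, label: str, path) -> None:
        self.digests[label] = sha256_file(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "version": self.version,
                 "seed": self.seed, "digests": self.digests,
                 "timestamp": self.timestamp},
                fh, indent=2, sort_keys=True,
            )
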