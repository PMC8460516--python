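"""Configuration loading and structured output: legacy VTK point clouds,
CSV summaries, JSON run reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import ParticleSet

__all__ = [
    "load_config",
    "save_config",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_csv",
    "write_report",
    "write_particle_csv",
    "ConfigError",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


class ConfigError(ValueError):
    pass


# Known configuration keys per application block; unknown keys are rejected.
_KNOWN_KEYS = {
    "application", "seed", "out_dir",
    "re", "n", "backend", "tol_picard", "max_picard", "lid_velocity",
    "eta", "nu", "gamma", "zeta", "lam", "dmu", "Ks", "Kb", "dt", "steps",
    "h", "l", "m", "amplitudes",
    "eps", "max_outer", "relax_p", "conv_order", "rc_factor",
}

_DEFAULTS = {
    "seed": 0,
    "rc_factor": 3.1,
    "conv_order": 2,
    "relax_p": 1.0,
    # benchmark active-fluid parameter set
    "eta": 1.0, "nu": -0.5, "gamma": 0.1, "zeta": 0.07,
    "lam": 0.1, "Ks": 1.0, "Kb": 1.0, "dmu": -1.0,
}


def load_config(path) -> dict:
    """Load and validate a JSON run configuration; fill defaults."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    for key in ("eta", "gamma", "dt", "eps", "h"):
        if key in cfg and cfg[key] is not None and not cfg[key] > 0:
            raise ConfigError(f"configuration field {key!r} must be positive")
    if "re" in cfg and cfg["re"] < 0:
        raise ConfigError("configuration field 're' must be >= 0")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# legacy VTK (ASCII POLYDATA point cloud)
# ---------------------------------------------------------------------------

def write_vtk_polydata(path, ps: ParticleSet, fields: dict | None = None,
                       title: str = "pdekit output") -> None:
    """Write particle positions and point data as legacy ASCII VTK POLYDATA.

    Scalars are written as SCALARS, (N, 3) / (N, 2) arrays as VECTORS
    (2-d vectors are zero-padded).  Values are printed with enough digits to
    round-trip float64.
    """
    fields = fields if fields is not None else ps.properties
    N = ps.N
    pos = ps.positions
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(N)])
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {N} double",
    ]
    for row in pos:
        lines.append(" ".join(_FLOAT_FMT % v for v in row))
    lines.append(f"VERTICES {N} {2 * N}")
    lines.extend(f"1 {i}" for i in range(N))
    data_fields = {k: v for k, v in fields.items() if v.ndim <= 2}
    if data_fields:
        lines.append(f"POINT_DATA {N}")
        for name, arr in data_fields.items():
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(_FLOAT_FMT % v for v in arr)
            else:
                vec = arr
                if vec.shape[1] == 2:
                    vec = np.column_stack([vec, np.zeros(N)])
                lines.append(f"VECTORS {name} double")
                for row in vec:
                    lines.append(" ".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Minimal reader for the files produced by :func:`write_vtk_polydata`.

    Returns ``(positions, fields)``.
    """
    tokens = Path(path).read_text().splitlines()
    i = 0
    positions = None
    fields = {}
    N = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            N = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * N:
                vals.extend(float(t) for t in tokens[i].split())
                i += 1
            positions = np.array(vals).reshape(N, 3)
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < N:
                vals.extend(float(t) for t in tokens[i].split())
                i += 1
            fields[name] = np.array(vals)
            continue
        if line.startswith("VECTORS"):
            name = line.split()[1]
            i += 1
            vals = []
            while len(vals) < 3 * N:
                vals.extend(float(t) for t in tokens[i].split())
                i += 1
            fields[name] = np.array(vals).reshape(N, 3)
            continue
        i += 1
    return positions, fields


# ---------------------------------------------------------------------------
# CSV / JSON
# ---------------------------------------------------------------------------

def write_csv(path, columns: dict) -> None:
    """Write named columns (equal length) as CSV with full precision."""
    names = list(columns)
    arrs = [np.asarray(columns[k]) for k in names]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("CSV columns must have equal length")
    with open(path, "w") as fh:
        fh.write(",".join(names) + "\n")
        for i in range(n):
            fh.write(",".join(_FLOAT_FMT % a[i] for a in arrs) + "\n")


def write_particle_csv(path, ps: ParticleSet, fields: dict | None = None) -> None:
    fields = fields if fields is not None else ps.properties
    cols = {}
    axes = "xyz"[: ps.d]
    for k, ax in enumerate(axes):
        cols[ax] = ps.positions[:, k]
    for name, arr in fields.items():
        if arr.ndim == 1:
            cols[name] = arr
        elif arr.ndim == 2:
            for k in range(arr.shape[1]):
                cols[f"{name}_{'xyz'[k]}"] = arr[:, k]
    write_csv(path, cols)


def write_report(path, report, extra: dict | None = None) -> None:
    """JSON run report: solver report plus arbitrary run metadata."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
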