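"""Configuration loading, deterministic CSV emission and run metadata.

Configs are TOML (preferred) or JSON with field names matching the
dataclasses; unknown keys are rejected with field-level messages.  All
writers emit byte-deterministic CSV (fixed column order, floats at 12
significant digits) plus a JSON sidecar recording the parameter hash, seed
and tolerances of the run.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .beaddrag import DragExperiment, MaterialLaw, RadialDisplacementProfile
from .disc import DiscModel, RadialFields
from .params import CellParameters, MatrixModel, ParameterError, PRESETS
from .sweeps import SweepResult

FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    """Schema violation in a config file."""


def _read_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _build(cls, data: dict, *, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**data)
    except ParameterError as exc:
        raise ConfigError(f"invalid [{section}]: {exc}") from exc


def load_cell_parameters(source) -> CellParameters:
    """Build CellParameters from a preset name, config path, or dict."""
    if isinstance(source, CellParameters):
        return source
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    data = source if isinstance(source, dict) else _read_config(source)
    data = dict(data.get("cell", data))
    if "preset" in data:
        preset = data.pop("preset")
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        return PRESETS[preset].replace(**data) if data else PRESETS[preset]
    return _build(CellParameters, data, section="cell")


def load_matrix(source) -> MatrixModel:
    data = source if isinstance(source, dict) else _read_config(source)
    return _build(MatrixModel, dict(data.get("matrix", data)), section="matrix")


def load_disc_model(source) -> DiscModel:
    data = source if isinstance(source, dict) else _read_config(source)
    data = dict(data.get("disc", data))
    if "cyto_params" in data:
        data["cyto_params"] = load_cell_parameters(data["cyto_params"])
    if "nuc_params" in data:
        data["nuc_params"] = load_cell_parameters(data["nuc_params"])
    return _build(DiscModel, data, section="disc")


def load_material_law(source) -> MaterialLaw:
    data = source if isinstance(source, dict) else _read_config(source)
    return _build(MaterialLaw, dict(data.get("law", data)), section="law")


def load_drag_experiment(source) -> DragExperiment:
    data = source if isinstance(source, dict) else _read_config(source)
    return _build(DragExperiment, dict(data.get("drag", data)), section="drag")


def _sidecar(path: Path, meta: dict) -> None:
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def _write_csv(frame: pd.DataFrame, path, meta: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)
    _sidecar(path, meta)
    return path


def emit_sweep(results: list[SweepResult], path, *, params_hash: str = "",
               seed: int | None = None, tol: float = 1e-10) -> Path:
    """Write genotype sweeps as CSV (genotype, k_m, sigma, rho, eps_m)."""
    frames = [
        pd.DataFrame({
            "genotype": res.genotype_label,
            "k_m": res.k_m_grid,
            "sigma": res.sigma,
            "rho": res.rho,
            "eps_m": res.eps_m,
        })
        for res in results
    ]
    frame = pd.concat(frames, ignore_index=True)
    return _write_csv(frame, path, {"params_hash": params_hash, "seed": seed, "tol": tol})


def emit_disc(fields: RadialFields, path, *, params_hash: str = "",
              seed: int | None = None, tol: float = 1e-9) -> Path:
    """Write disc fields as CSV (r, u, sigma_rr, sigma_tt, sigma_c, sigma_t, rho)."""
    frame = pd.DataFrame({
        "r": fields.r, "u": fields.u,
        "sigma_rr": fields.sigma_rr, "sigma_tt": fields.sigma_tt,
        "sigma_c": fields.sigma_c, "sigma_t": fields.sigma_t,
        "rho": fields.rho,
    })
    meta = {"params_hash": params_hash, "seed": seed, "tol": tol,
            "residual": fields.residual, "iterations": fields.iterations}
    return _write_csv(frame, path, meta)


def emit_profile(profile: RadialDisplacementProfile, path, *, params_hash: str = "",
                 seed: int | None = None) -> Path:
    """Write a bead-drag profile as CSV (x, u, strain)."""
    frame = pd.DataFrame({"x": profile.x, "u": profile.u, "strain": profile.strain})
    meta = {"params_hash": params_hash, "seed": seed,
            "transmitted_force": profile.transmitted_force}
    return _write_csv(frame, path, meta)


def emit_traces(traces, path, *, seed: int | None = None) -> Path:
    """Write filament traces as CSV (filament_id, x, y)."""
    frames = [
        pd.DataFrame({"filament_id": t.label or str(i),
                      "x": t.points[:, 0], "y": t.points[:, 1]})
        for i, t in enumerate(traces)
    ]
    frame = pd.concat(frames, ignore_index=True)
    return _write_csv(frame, path, {"seed": seed, "n_traces": len(list(traces))})


def read_traces(path):
    """Read filament traces back from a (filament_id, x, y) CSV."""
    from .filaments import FilamentTrace

    frame = pd.read_csv(path)
    traces = []
    for fid, grp in frame.groupby("filament_id", sort=False):
        traces.append(FilamentTrace(points=np.column_stack([grp["x"], grp["y"]]),
                                    label=str(fid)))
    return traces
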