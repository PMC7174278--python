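"""File formats: CSV spectra/run/LOD dialects and JSON model serialization.

All formats are plain text.  A spectra file is CSV with a ``timestamp``
column followed by one column per wavelength (the header row carries the
wavelengths); intensity data require a JSON sidecar (``<stem>.refs.json``)
holding the bright/dark reference spectra.  Floats are written with 17
significant digits so every round trip is lossless to 1e-15.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    BedConfig,
    DryingRun,
    Formulation,
    GABParams,
    MSPCModel,
    PLSModel,
    ResistanceFit,
    SpectraSeries,
)

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_run",
    "write_run",
    "read_lod",
    "write_lod",
    "load_formulation",
    "pls_to_json",
    "pls_from_json",
    "mspc_to_json",
    "mspc_from_json",
    "resistance_to_json",
    "resistance_from_json",
]

_FLOAT_FMT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".refs.json")


def write_spectra(series: SpectraSeries, path: Union[str, Path]) -> None:
    """Write a SpectraSeries as CSV plus a JSON sidecar for references/metadata."""
    path = Path(path)
    df = pd.DataFrame(series.values, columns=[repr(float(w)) for w in series.wavelengths])
    df.insert(0, "timestamp", series.timestamps)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "kind": series.kind,
        "bright_ref": None if series.bright_ref is None else series.bright_ref.tolist(),
        "dark_ref": None if series.dark_ref is None else series.dark_ref.tolist(),
        "meta": _json_safe(series.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_spectra(path: Union[str, Path], validate_grid: Optional[int] = None) -> SpectraSeries:
    """Read a spectra CSV + sidecar back into a SpectraSeries.

    ``validate_grid`` optionally enforces an exact wavelength count (e.g. the
    401-point sensor grid).
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side.name} (bright/dark references) for {path.name}"
        )
    info = json.loads(side.read_text())
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spectra CSV {path.name}: {exc}") from exc
    if "timestamp" not in df.columns:
        raise ValueError(f"{path.name}: first column must be 'timestamp'")
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    if validate_grid is not None and wavelengths.size != validate_grid:
        raise ValueError(
            f"{path.name}: expected {validate_grid} wavelength columns, "
            f"found {wavelengths.size}"
        )
    kind = info.get("kind", "intensity")
    if kind == "intensity" and (info.get("bright_ref") is None or info.get("dark_ref") is None):
        raise ValueError(f"{side.name}: intensity data require bright and dark references")
    return SpectraSeries(
        wavelengths=wavelengths,
        timestamps=df["timestamp"].to_numpy(),
        values=df.iloc[:, 1:].to_numpy(),
        kind=kind,
        bright_ref=None if info.get("bright_ref") is None else np.array(info["bright_ref"]),
        dark_ref=None if info.get("dark_ref") is None else np.array(info["dark_ref"]),
        meta=info.get("meta", {}),
    )


def write_run(run: DryingRun, path: Union[str, Path]) -> None:
    """Write a drying run as CSV (time, f_w, F_w, T_bed, T_in) + JSON metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": run.time,
            "f_w": run.moisture_fraction,
            "F_w": run.dry_basis_moisture,
            "T_bed": run.bed_temp,
            "T_in": run.inlet_temp,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "bed": dataclasses.asdict(run.bed),
        "lod_samples": [[t, v] for t, v in run.lod_samples],
        "meta": _json_safe(run.meta),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_run(path: Union[str, Path]) -> DryingRun:
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path.name}")
    info = json.loads(meta_path.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    return DryingRun(
        time=df["time"].to_numpy(),
        moisture_fraction=df["f_w"].to_numpy(),
        bed_temp=df["T_bed"].to_numpy(),
        inlet_temp=df["T_in"].to_numpy(),
        bed=BedConfig(**info["bed"]),
        lod_samples=[(t, v) for t, v in info.get("lod_samples", [])],
        meta=info.get("meta", {}),
    )


def write_lod(samples: list[tuple[float, float]], path: Union[str, Path]) -> None:
    pd.DataFrame(samples, columns=["time", "f_w"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_lod(path: Union[str, Path]) -> list[tuple[float, float]]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [(float(t), float(v)) for t, v in zip(df["time"], df["f_w"])]


def load_formulation(path: Optional[Union[str, Path]] = None) -> Formulation:
    """Load a formulation from JSON; defaults to the packaged placebo granule."""
    if path is None:
        text = resources.files("granudry.data").joinpath("placebo_formulation.json").read_text()
    else:
        text = Path(path).read_text()
    info = json.loads(text)
    comps = [GABParams(**c) for c in info["components"]]
    return Formulation(components=comps, adsorbing_subset=info["adsorbing_subset"])


# ---------------------------------------------------------------------------
# model serialization


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def pls_to_json(model: PLSModel, path: Union[str, Path]) -> None:
    payload = {
        "n_lv": model.n_lv,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "b": model.b.tolist(),
        "b0": model.b0,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "wavelength_grid": model.wavelength_grid.tolist(),
        "residuals": model.residuals.tolist(),
        "meta": _json_safe(model.meta),
    }
    Path(path).write_text(json.dumps(payload))


def pls_from_json(path: Union[str, Path]) -> PLSModel:
    d = json.loads(Path(path).read_text())
    return PLSModel(
        n_lv=d["n_lv"],
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        b=np.array(d["b"]),
        b0=d["b0"],
        x_mean=np.array(d["x_mean"]),
        y_mean=d["y_mean"],
        wavelength_grid=np.array(d["wavelength_grid"]),
        residuals=np.array(d["residuals"]),
        meta=d.get("meta", {}),
    )


def mspc_to_json(model: MSPCModel, path: Union[str, Path]) -> None:
    payload = {
        "loadings": model.loadings.tolist(),
        "x_mean": model.x_mean.tolist(),
        "n_pc": model.n_pc,
        "residual_eigenvalues": model.residual_eigenvalues.tolist(),
        "limit_95": model.limit_95,
        "limit_99": model.limit_99,
        "snv_applied": model.snv_applied,
        "wavelength_grid": None if model.wavelength_grid is None
        else model.wavelength_grid.tolist(),
        "meta": _json_safe(model.meta),
    }
    Path(path).write_text(json.dumps(payload))


def mspc_from_json(path: Union[str, Path]) -> MSPCModel:
    d = json.loads(Path(path).read_text())
    return MSPCModel(
        loadings=np.array(d["loadings"]),
        x_mean=np.array(d["x_mean"]),
        n_pc=d["n_pc"],
        residual_eigenvalues=np.array(d["residual_eigenvalues"]),
        limit_95=d["limit_95"],
        limit_99=d["limit_99"],
        snv_applied=d["snv_applied"],
        wavelength_grid=None if d.get("wavelength_grid") is None
        else np.array(d["wavelength_grid"]),
        meta=d.get("meta", {}),
    )


def resistance_to_json(fit: ResistanceFit, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(fit)))


def resistance_from_json(path: Union[str, Path]) -> ResistanceFit:
    return ResistanceFit(**json.loads(Path(path).read_text()))
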