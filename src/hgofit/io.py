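"""File formats: curve CSV, material-parameter JSON, fit-result JSON.

Curves travel as two-column CSV (``strain,stress_mpa``) with an optional
leading comment line ``# mode=tension region=anterior`` carrying the
metadata.  Material parameters use a flat JSON schema with explicit units
in the key names.  Angles are exchanged in degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import AngleSample
from .calibration import FitResult
from .constitutive import (
    FiberParams,
    GroundParams,
    MaterialRegion,
    ParameterError,
)
from .specimen import StressStrainCurve

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "material_to_dict",
    "material_from_dict",
    "write_material_json",
    "read_material_json",
    "write_fit_result_json",
    "read_angles_csv",
]


def write_curve_csv(curve: StressStrainCurve, path) -> None:
    path = Path(path)
    meta = f"# mode={curve.mode}"
    if curve.region:
        meta += f" region={curve.region}"
    lines = [meta, "strain,stress_mpa"]
    for e, s in zip(curve.strains, curve.stresses):
        lines.append(f"{e:.10g},{s:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_curve_csv(path, mode: str | None = None) -> StressStrainCurve:
    """Read a curve CSV; the mode comes from the comment line or ``mode``."""
    path = Path(path)
    region = None
    file_mode = None
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("mode="):
                file_mode = token[5:]
            elif token.startswith("region="):
                region = token[7:]
    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "strain" not in cols or "stress_mpa" not in cols:
        raise ParameterError(f"{path}: expected columns strain,stress_mpa")
    use_mode = mode or file_mode
    if use_mode is None:
        raise ParameterError(f"{path}: curve mode not recorded; pass mode=")
    return StressStrainCurve(
        use_mode,
        df["strain"].to_numpy(float),
        df["stress_mpa"].to_numpy(float),
        region=region,
    )


def material_to_dict(mr: MaterialRegion) -> dict:
    return {
        "region": mr.region,
        "C10_MPa": mr.ground.C10,
        "D_per_MPa": mr.ground.D,
        "k1_MPa": mr.fibers.k1,
        "k2": mr.fibers.k2,
        "kappa": mr.fibers.kappa,
        "theta_deg": mr.fibers.theta_deg,
    }


def material_from_dict(d: dict) -> MaterialRegion:
    return MaterialRegion(
        region=d["region"],
        ground=GroundParams(float(d["C10_MPa"]), float(d["D_per_MPa"])),
        fibers=FiberParams(
            k1=float(d["k1_MPa"]), k2=float(d["k2"]),
            kappa=float(d.get("kappa", 0.01)),
            theta_deg=float(d["theta_deg"]),
        ),
    )


def write_material_json(mr: MaterialRegion, path) -> None:
    Path(path).write_text(json.dumps(material_to_dict(mr), indent=2) + "\n")


def read_material_json(path) -> MaterialRegion:
    return material_from_dict(json.loads(Path(path).read_text()))


def write_fit_result_json(fit: FitResult, path, include_trace: bool = True) -> None:
    """Persist a fit result; the full grid trace is kept for audit."""
    payload = {
        "params": fit.params,
        "objective_mse_mpa2": fit.objective,
        "r_squared": fit.r_squared,
        "boundary": bool(fit.boundary),
    }
    if include_trace:
        payload["trace"] = fit.trace.to_dict(orient="list")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_angles_csv(path) -> dict[str, AngleSample]:
    """Read ``region,angle_deg`` CSV into per-region angle samples."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "region" not in df.columns or "angle_deg" not in df.columns:
        raise ParameterError(f"{path}: expected columns region,angle_deg")
    out = {}
    for region, grp in df.groupby("region"):
        out[str(region)] = AngleSample(str(region),
                                       tuple(grp["angle_deg"].astype(float)))
    return out
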