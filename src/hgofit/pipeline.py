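"""End-to-end two-stage characterization pipeline.

A config (YAML or JSON) names per-region compression/tension curve files,
the parameter grids, and the fixed constants (nu = 0.49, kappa = 0.01,
theta per region); :func:`run_pipeline` fits every region and writes the
calibrated material JSONs, the fit results with full grid traces, and a
report embedding the seed, package version, and a hash of the resolved
config, so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calibration import GridSpec, RegionFitConfig, fit_region_pipeline
from .constitutive import ParameterError
from .io import (
    material_to_dict,
    read_curve_csv,
    write_fit_result_json,
    write_material_json,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

_DEFAULT_GRIDS = {
    "e": {"min": 0.1, "max": 3.0, "step": 0.01},
    "k1": {"min": 1.0, "max": 45.0, "step": 1.0},
    "k2": {"min": 50.0, "max": 2000.0, "step": 30.0},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration.

    regions : mapping region -> {"compression": path, "tension": path,
        "theta_deg": float}; the tension entry may be absent.
    grids : mapping {"e"|"k1"|"k2"} -> {"min","max","step"}.
    """

    regions: dict
    grids: dict = field(default_factory=lambda: dict(_DEFAULT_GRIDS))
    nu: float = 0.49
    kappa: float = 0.01
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ParameterError("pipeline config names no regions")

    def grid(self, name: str) -> GridSpec:
        g = {**_DEFAULT_GRIDS[name], **self.grids.get(name, {})}
        return GridSpec.from_step(name, g["min"], g["max"], g["step"])

    def canonical_json(self) -> str:
        return json.dumps(
            {"regions": self.regions, "grids": self.grids, "nu": self.nu,
             "kappa": self.kappa, "seed": self.seed},
            sort_keys=True,
        )


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "regions" not in raw:
        raise ParameterError(f"{path}: config must define a 'regions' mapping")
    return PipelineConfig(
        regions=raw["regions"],
        grids=raw.get("grids", dict(_DEFAULT_GRIDS)),
        nu=float(raw.get("nu", 0.49)),
        kappa=float(raw.get("kappa", 0.01)),
        out_dir=str(raw.get("out_dir", ".")),
        seed=int(raw.get("seed", 0)),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Fit every configured region; write materials, fits, and a report.

    Returns the report dict.  Regions with a missing tension curve fall
    back to a ground-only material with a warning; a missing compression
    curve is an error for that region (recorded, pipeline continues).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "hgofit",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "regions": {},
    }
    for region, spec in sorted(config.regions.items()):
        entry: dict = {}
        try:
            comp = read_curve_csv(spec["compression"], mode="compression")
            tens = None
            if spec.get("tension"):
                tens = read_curve_csv(spec["tension"], mode="tension")
            cfg = RegionFitConfig(
                e_grid=config.grid("e"),
                k1_grid=config.grid("k1"),
                k2_grid=config.grid("k2"),
                theta_deg=float(spec["theta_deg"]),
                nu=config.nu,
                kappa=config.kappa,
                region=region,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                material, fit_report = fit_region_pipeline(comp, tens, cfg)
            entry["warnings"] = [str(w.message) for w in caught]
            write_material_json(material, out_dir / f"{region}_material.json")
            write_fit_result_json(fit_report["ground_fit"],
                                  out_dir / f"{region}_ground_fit.json")
            if fit_report["fiber_fit"] is not None:
                write_fit_result_json(fit_report["fiber_fit"],
                                      out_dir / f"{region}_fiber_fit.json")
            entry.update({
                "material": material_to_dict(material),
                "ground_r_squared": fit_report["ground_r_squared"],
                "fiber_r_squared": fit_report["fiber_r_squared"],
                "ground_boundary": fit_report["ground_fit"].boundary,
                "fiber_boundary": (fit_report["fiber_fit"].boundary
                                   if fit_report["fiber_fit"] else None),
                "status": "ok",
            })
        except (OSError, KeyError, ParameterError) as exc:
            entry.update({"status": "error", "message": str(exc)})
        report["regions"][region] = entry
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
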