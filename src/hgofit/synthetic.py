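"""Synthetic data generation emulating the characterization inputs.

Every pipeline stage is testable without external downloads: forward
simulation of stress-strain curves with an optional multiplicative
Gaussian noise model (experimental scatter in soft-tissue stress data
grows with the stress level, hence relative rather than additive noise),
rejection-sampled Gaussian fiber-angle samples, and a bundled fixture set
carrying the reported regional material parameters, median tensile yield
anchors, and fiber-angle statistics of the ovine lumbar annulus study
this package re-implements.

An importer for the study's supplementary spreadsheet (sheets
'Little data', 'Anterior', 'Lateral', 'Posterior') is provided for users
who supply that optional file; it is never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import AngleSample
from .constitutive import (
    FiberParams,
    GroundParams,
    MaterialRegion,
    ParameterError,
)
from .specimen import (
    DEFAULT_COMPRESSION_STRAINS,
    DEFAULT_TENSION_STRAINS,
    SolverSettings,
    StressStrainCurve,
    simulate_compression,
    simulate_tension,
)

__all__ = [
    "NoiseModel",
    "ReferenceData",
    "generate_curve",
    "generate_angles",
    "reference_fixtures",
    "load_supplementary_workbook",
]


@dataclass(frozen=True)
class NoiseModel:
    """Reproducible noise on simulated stresses.

    kind : "none" or "multiplicative_gaussian"; the latter perturbs each
        stress by a factor (1 + e), e ~ Normal(0, sigma^2) clipped at
        -0.9 so stresses stay positive.
    sigma : relative SD, dimensionless (default 0.05).
    seed : integer seed; identical seeds give identical curves.
    """

    kind: str = "multiplicative_gaussian"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_gaussian"):
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0.0:
            raise ParameterError("sigma must be non-negative")


def generate_curve(
    mr: MaterialRegion,
    mode: str,
    strain_levels=None,
    noise: NoiseModel | None = None,
    settings: SolverSettings | None = None,
) -> StressStrainCurve:
    """Forward-simulate a specimen curve and optionally add noise.

    ``mode='compression'`` simulates the bare ground substance (the
    compression protocol characterizes the matrix alone);
    ``mode='tension'`` the full fiber-reinforced material.  With
    ``noise=None`` or kind "none" the exact forward curve is returned.
    """
    if mode == "compression":
        levels = DEFAULT_COMPRESSION_STRAINS if strain_levels is None else strain_levels
        curve = simulate_compression(mr.ground, levels, settings=settings,
                                     region=mr.region)
    elif mode == "tension":
        levels = DEFAULT_TENSION_STRAINS if strain_levels is None else strain_levels
        curve = simulate_tension(mr, levels, settings=settings)
    else:
        raise ParameterError(f"mode must be compression or tension, got {mode!r}")
    if noise is None or noise.kind == "none" or noise.sigma == 0.0:
        return curve
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.sigma, size=curve.stresses.shape)
    eps = np.maximum(eps, -0.9)
    noisy = curve.stresses * (1.0 + eps)
    return StressStrainCurve(curve.mode, curve.strains, noisy,
                             region=curve.region,
                             metadata=dict(curve.metadata, noise_sigma=noise.sigma,
                                           noise_seed=noise.seed))


def generate_angles(mean_deg: float, sd_deg: float, n: int, seed: int = 0,
                    region: str = "anterior") -> AngleSample:
    """Draw ``n`` Gaussian fiber angles, rejection-resampled into (0, 90)."""
    if n < 1:
        raise ParameterError("n must be at least 1")
    if not (0.0 < mean_deg < 90.0):
        raise ParameterError("mean angle must lie in (0, 90) degrees")
    rng = np.random.default_rng(seed)
    if sd_deg == 0.0:
        vals = np.full(n, mean_deg)
    else:
        vals = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mean_deg, sd_deg, size=n - filled)
            keep = draw[(draw > 0.0) & (draw < 90.0)]
            vals[filled:filled + keep.size] = keep
            filled += keep.size
    return AngleSample(region=region, measurements=tuple(vals))


@dataclass(frozen=True)
class ReferenceData:
    """Bundled reference values of the ovine annulus characterization.

    regions : calibrated material parameters per annulus region.
    nucleus : Neo-Hookean parameters of the nucleus pulposus.
    yield_anchors : per region, (strain, median yield stress MPa, SD MPa)
        of the tensile tests.
    angle_stats : per region, (mean, SD) of the fiber angle in degrees.
    ground_moduli : per region, fitted ground-substance Young modulus, MPa.
    specimen_moduli : per region, (tangent modulus MPa, SD) of the tensile
        specimens.
    provenance : per field, where the value was reported.
    """

    regions: dict
    nucleus: GroundParams
    yield_anchors: dict
    angle_stats: dict
    ground_moduli: dict
    specimen_moduli: dict
    provenance: dict


def reference_fixtures() -> ReferenceData:
    """Reported values of the source characterization study."""
    kappa = 0.01
    regions = {
        "anterior": MaterialRegion(
            "anterior", GroundParams(0.061, 0.311),
            FiberParams(24.0, 1700.0, kappa, 29.0)),
        "lateral": MaterialRegion(
            "lateral", GroundParams(0.033, 0.615),
            FiberParams(5.0, 940.0, kappa, 30.0)),
        "posterior": MaterialRegion(
            "posterior", GroundParams(0.077, 0.261),
            FiberParams(1.0, 50.0, kappa, 28.0)),
    }
    return ReferenceData(
        regions=regions,
        nucleus=GroundParams(0.168, 0.12),
        yield_anchors={
            "anterior": (0.5, 2.85, 0.79),
            "lateral": (0.6, 1.95, 0.86),
            "posterior": (0.6, 2.06, 0.26),
        },
        angle_stats={
            "anterior": (29.0, 3.9),
            "lateral": (30.0, 4.0),
            "posterior": (28.0, 4.1),
        },
        ground_moduli={"anterior": 0.38, "lateral": 0.26, "posterior": 0.46},
        specimen_moduli={
            "anterior": (5.6, 1.4), "lateral": (2.6, 1.2), "posterior": (2.7, 0.6),
        },
        provenance={
            "regions": "published material-parameter table of the source study",
            "nucleus": "published material-parameter table (nucleus pulposus row)",
            "yield_anchors": "reported median yield stresses of the tensile tests",
            "angle_stats": "reported fiber-angle means and SDs from MR measurements",
            "ground_moduli": "reported ground-substance Young moduli per region",
            "specimen_moduli": "reported tangent moduli of the tensile specimens",
        },
    )


# ---------------------------------------------------------------------------
# Optional supplementary-spreadsheet importer
# ---------------------------------------------------------------------------

_TENSION_SHEETS = ("Anterior", "Lateral", "Posterior")


def _find_curve_columns(df):
    """Locate a strain column and one or more stress columns by header."""
    import pandas as pd  # local import keeps openpyxl optional at import time

    cols = {str(c).strip().lower(): c for c in df.columns}
    strain_col = None
    for key, c in cols.items():
        if "strain" in key:
            strain_col = c
            break
    if strain_col is None:
        raise ParameterError("no strain column found in sheet")
    stress_cols = [c for c in df.columns if c is not strain_col
                   and pd.api.types.is_numeric_dtype(df[c])]
    return strain_col, stress_cols


def load_supplementary_workbook(path) -> dict:
    """Read the optional supplementary spreadsheet into curves.

    Expected layout: a 'Little data' sheet with a strain column and one
    stress column per region (headers containing 'anterior', 'lateral',
    'posterior'; compression data), plus 'Anterior' / 'Lateral' /
    'Posterior' sheets each holding a strain column and a median stress
    column (tension data).  Returns
    ``{"compression": {region: curve}, "tension": {region: curve}}``;
    sheets that are absent are simply skipped.
    """
    import pandas as pd

    book = pd.read_excel(path, sheet_name=None)
    out: dict = {"compression": {}, "tension": {}}

    little = next((s for s in book if s.strip().lower() == "little data"), None)
    if little is not None:
        df = book[little].dropna(how="all")
        strain_col, stress_cols = _find_curve_columns(df)
        for c in stress_cols:
            name = str(c).strip().lower()
            for region in ("anterior", "lateral", "posterior"):
                if region in name:
                    sub = df[[strain_col, c]].dropna()
                    sub = sub[sub[strain_col] >= 0].sort_values(strain_col)
                    out["compression"][region] = StressStrainCurve(
                        "compression",
                        sub[strain_col].to_numpy(float),
                        np.abs(sub[c].to_numpy(float)),
                        region=region,
                    )
    for sheet in _TENSION_SHEETS:
        name = next((s for s in book if s.strip().lower() == sheet.lower()), None)
        if name is None:
            continue
        df = book[name].dropna(how="all")
        strain_col, stress_cols = _find_curve_columns(df)
        if not stress_cols:
            continue
        sub = df[[strain_col, stress_cols[0]]].dropna()
        sub = sub[sub[strain_col] >= 0].sort_values(strain_col)
        out["tension"][sheet.lower()] = StressStrainCurve(
            "tension",
            sub[strain_col].to_numpy(float),
            np.abs(sub[stress_cols[0]].to_numpy(float)),
            region=sheet.lower(),
        )
    return out
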