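"""Full-factorial grid-search calibration of H-G-O parameters.

Two-stage identification mirroring the characterization protocol:

1. ``fit_ground`` — the Neo-Hookean matrix is fitted to a uniaxial
   compression curve by sweeping the equivalent Young modulus E on a grid
   at fixed Poisson ratio (0.49), converting each E to (C10, D) and
   scoring the simulated curve by mean squared stress error.
2. ``fit_fibers`` — with the matrix frozen, the fiber pair (k1, k2) is
   swept on a full-factorial grid against a uniaxial tension curve, at
   fixed dispersion kappa and measured fiber angle theta.

Both fits are exhaustive: every grid point is evaluated (vectorized in one
batched solve), the full trace is kept for audit, ties are broken toward
the softest material, and a boundary flag marks optima on a grid edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (
    ElasticConstants,
    FiberParams,
    GroundParams,
    MaterialRegion,
    ParameterError,
    elastic_to_ground,
)
from .specimen import (
    SolverSettings,
    StressStrainCurve,
    simulate_curve_batch,
)

__all__ = [
    "GridSpec",
    "FitResult",
    "RegionFitConfig",
    "mse",
    "r_squared",
    "fit_ground",
    "fit_fibers",
    "fit_region_pipeline",
]


@dataclass(frozen=True)
class GridSpec:
    """Explicit strictly increasing grid of values for one parameter."""

    name: str
    values: tuple

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, float)
        if vals.ndim != 1 or vals.size < 1:
            raise ParameterError(f"grid {self.name!r} must hold at least one value")
        if vals.size > 1 and not np.all(np.diff(vals) > 0):
            raise ParameterError(f"grid {self.name!r} must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @classmethod
    def from_range(cls, name: str, lo: float, hi: float, count: int) -> "GridSpec":
        """Linearly spaced grid with ``count`` points on [lo, hi]."""
        return cls(name, tuple(np.linspace(lo, hi, count)))

    @classmethod
    def from_step(cls, name: str, lo: float, hi: float, step: float) -> "GridSpec":
        """Grid lo, lo+step, ... up to hi (inclusive within rounding)."""
        n = int(round((hi - lo) / step))
        return cls(name, tuple(lo + step * np.arange(n + 1)))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FitResult:
    """Outcome of one exhaustive grid search.

    ``trace`` holds every evaluated combination with its objective; the
    reported minimum is the minimum of the trace by construction.
    ``boundary`` is True when the best point lies on any edge of the grid,
    a warning that the true optimum may sit outside the searched range.
    """

    params: dict
    objective: float
    r_squared: float
    trace: pd.DataFrame
    boundary: bool

    def __post_init__(self) -> None:
        finite = self.trace["mse"].to_numpy()
        finite = finite[np.isfinite(finite)]
        if finite.size and self.objective > finite.min() + 1e-15:
            raise ParameterError("reported objective is not the trace minimum")


@dataclass(frozen=True)
class RegionFitConfig:
    """Grids and fixed constants for a two-stage regional fit."""

    e_grid: GridSpec
    k1_grid: GridSpec
    k2_grid: GridSpec
    theta_deg: float
    nu: float = 0.49
    kappa: float = 0.01
    region: str = "anterior"


def mse(observed: StressStrainCurve, predicted: StressStrainCurve) -> float:
    """Mean squared stress residual, MPa^2, at matched strain levels."""
    if len(observed) != len(predicted) or not np.allclose(
        observed.strains, predicted.strains, rtol=0.0, atol=1e-12
    ):
        raise ParameterError("curves must share the same strain grid")
    r = observed.stresses - predicted.stresses
    return float(np.mean(r * r))


def r_squared(observed: StressStrainCurve, predicted: StressStrainCurve) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of the observed stresses; a prediction
    worse than that mean yields a negative value.
    """
    if len(observed) < 2:
        raise ParameterError("r_squared needs at least two points")
    if len(observed) != len(predicted) or not np.allclose(
        observed.strains, predicted.strains, rtol=0.0, atol=1e-12
    ):
        raise ParameterError("curves must share the same strain grid")
    obs = observed.stresses
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ParameterError("observed stresses have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - predicted.stresses) ** 2))
    return 1.0 - ss_res / ss_tot


def _mse_array(target: StressStrainCurve, stresses: np.ndarray) -> np.ndarray:
    """Vectorized MSE of (n_levels, n_batch) predictions; nan -> inf."""
    r = stresses - target.stresses[:, None]
    out = np.mean(r * r, axis=0)
    return np.where(np.isfinite(out), out, np.inf)


def fit_ground(
    target: StressStrainCurve,
    e_grid: GridSpec,
    nu: float = 0.49,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Fit the Neo-Hookean matrix to a compression curve by sweeping E.

    Every E on the grid is converted to (C10, D) at the fixed Poisson
    ratio, the compression test is simulated at the target's strain
    levels, and the mean squared stress error is scored.  Ties break
    toward the smallest E; simulation failures score ``inf`` and never
    abort the sweep.
    """
    if target.mode != "compression":
        raise ParameterError("fit_ground expects a compression curve")
    e_vals = e_grid.array
    c10 = e_vals / (4.0 * (1.0 + nu))
    d = 6.0 * (1.0 - 2.0 * nu) / e_vals
    stresses, _ = simulate_curve_batch(
        c10, d, np.zeros_like(c10), 1.0, 0.0, 0.0,
        target.strains, "compression", settings,
    )
    obj = _mse_array(target, stresses)
    best = int(np.argmin(obj))  # first minimum = smallest E
    trace = pd.DataFrame({"E": e_vals, "C10": c10, "D": d, "mse": obj})
    pred = StressStrainCurve("compression", target.strains, stresses[:, best])
    return FitResult(
        params={"E": float(e_vals[best]), "nu": nu,
                "C10": float(c10[best]), "D": float(d[best])},
        objective=float(obj[best]),
        r_squared=r_squared(target, pred),
        trace=trace,
        boundary=(best == 0 or best == len(e_vals) - 1),
    )


def fit_fibers(
    target: StressStrainCurve,
    ground: GroundParams,
    theta_deg: float,
    k1_grid: GridSpec,
    k2_grid: GridSpec,
    kappa: float = 0.01,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Fit (k1, k2) to a tension curve on a full-factorial grid.

    The matrix parameters come frozen from the compression stage.  The
    whole k1 x k2 lattice is simulated in one batched solve; ties break
    toward smaller k1, then smaller k2.
    """
    if target.mode != "tension":
        raise ParameterError("fit_fibers expects a tension curve")
    k1v, k2v = k1_grid.array, k2_grid.array
    K1, K2 = np.meshgrid(k1v, k2v, indexing="ij")
    stresses, _ = simulate_curve_batch(
        ground.C10, ground.D, K1, K2, kappa, np.radians(theta_deg),
        target.strains, "tension", settings,
    )
    flat = stresses.reshape(stresses.shape[0], -1)  # row-major: k1 outer
    obj = _mse_array(target, flat)
    best = int(np.argmin(obj))
    i1, i2 = divmod(best, len(k2v))
    trace = pd.DataFrame({
        "k1": K1.ravel(), "k2": K2.ravel(), "mse": obj,
    })
    pred = StressStrainCurve("tension", target.strains, flat[:, best])
    boundary = (
        i1 in (0, len(k1v) - 1) or i2 in (0, len(k2v) - 1)
    )
    return FitResult(
        params={"k1": float(k1v[i1]), "k2": float(k2v[i2]),
                "kappa": kappa, "theta_deg": theta_deg},
        objective=float(obj[best]),
        r_squared=r_squared(target, pred),
        trace=trace,
        boundary=boundary,
    )


def fit_region_pipeline(
    compression_target: StressStrainCurve | None,
    tension_target: StressStrainCurve | None,
    config: RegionFitConfig,
    settings: SolverSettings | None = None,
) -> tuple[MaterialRegion, dict]:
    """Two-stage regional characterization: matrix fit, then fiber fit.

    Returns the calibrated :class:`MaterialRegion` and a report dict with
    both :class:`FitResult` objects and their R^2 values.  A missing
    tension curve degrades gracefully to a matrix-only material with
    k1 = 0 and a warning.
    """
    if compression_target is None:
        raise ParameterError("a compression curve is required for the matrix stage")
    ground_fit = fit_ground(compression_target, config.e_grid, config.nu, settings)
    ground = GroundParams(ground_fit.params["C10"], ground_fit.params["D"])
    report: dict = {
        "ground_fit": ground_fit,
        "ground_r_squared": ground_fit.r_squared,
        "fiber_fit": None,
        "fiber_r_squared": None,
    }
    if tension_target is None:
        warnings.warn(
            "no tension curve supplied: returning a ground-only material with k1=0",
            stacklevel=2,
        )
        fibers = FiberParams(k1=0.0, k2=1.0, kappa=config.kappa,
                             theta_deg=config.theta_deg)
    else:
        fiber_fit = fit_fibers(
            tension_target, ground, config.theta_deg,
            config.k1_grid, config.k2_grid, config.kappa, settings,
        )
        report["fiber_fit"] = fiber_fit
        report["fiber_r_squared"] = fiber_fit.r_squared
        fibers = FiberParams(
            k1=fiber_fit.params["k1"], k2=fiber_fit.params["k2"],
            kappa=config.kappa, theta_deg=config.theta_deg,
        )
    region = MaterialRegion(region=config.region, ground=ground, fibers=fibers)
    return region, report
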