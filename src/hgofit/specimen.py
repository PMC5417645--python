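"""Virtual uniaxial specimen tests as homogeneous deformations.

The physical tests stretch or compress a block of annulus tissue along the
spine axis with free lateral faces.  Away from the grips the deformation is
homogeneous, so the specimen response is modelled as a single triaxial
stretch state diag(l_t1, l_t2, l_axial) whose transverse stretches are
solved so that both transverse nominal stresses vanish.  The axial nominal
stress is then dU/d(l_axial) per unit reference area — identical, by the
envelope theorem, to the derivative of the relaxed (transverse-equilibrated)
energy with respect to the axial stretch.

The transverse equilibrium is found by a damped Newton iteration, batched
over arbitrarily many parameter sets at once so that full-factorial
calibration grids are solved in a handful of vectorized iterations.
Continuation in the axial strain (small internal substeps, each started
from the previous solution) keeps the iteration on the physical branch even
for the stiffest exponential fiber parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import (
    FiberParams,
    GroundParams,
    KinematicState,
    MaterialRegion,
    ParameterError,
    fiber_strain,
    kinematics_uniaxial,
    nominal_stress_components,
)

__all__ = [
    "SolverError",
    "SolverSettings",
    "StressStrainCurve",
    "DEFAULT_COMPRESSION_STRAINS",
    "DEFAULT_TENSION_STRAINS",
    "solve_uniaxial_state",
    "simulate_compression",
    "simulate_tension",
    "simulate_curve_batch",
    "tangent_modulus",
]

#: Imposed engineering-strain levels of the compression protocol (fractions
#: of specimen height).
DEFAULT_COMPRESSION_STRAINS = (0.10, 0.15, 0.20, 0.25, 0.30)
#: Imposed engineering-strain levels of the tension protocol.
DEFAULT_TENSION_STRAINS = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60)


class SolverError(RuntimeError):
    """Transverse equilibrium could not be reached within tolerance."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the transverse-equilibrium solver.

    tol : residual tolerance on each transverse nominal stress, MPa.
    max_iter : Newton iterations per continuation substep.
    max_substep : largest engineering-strain increment between substeps;
        the initial guess at each substep is the previous solution
        (identity at the start).
    """

    tol: float = 1e-9
    max_iter: int = 80
    max_substep: float = 0.02

    def __post_init__(self) -> None:
        if not (self.tol > 0.0):
            raise ParameterError("solver tolerance must be positive")


@dataclass
class StressStrainCurve:
    """Nominal stress-strain curve of a uniaxial test.

    ``strains`` and ``stresses`` hold positive magnitudes (engineering
    strain, nominal stress in MPa) regardless of mode; ``metadata`` carries
    auxiliary flags such as fiber activation in compression.
    """

    mode: str
    strains: np.ndarray
    stresses: np.ndarray
    region: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, float)
        self.stresses = np.asarray(self.stresses, float)
        if self.mode not in ("compression", "tension"):
            raise ParameterError(f"mode must be compression or tension, got {self.mode!r}")
        if self.strains.shape != self.stresses.shape or self.strains.ndim != 1:
            raise ParameterError("strains and stresses must be 1-d arrays of equal length")
        if self.strains.size > 1 and not np.all(np.diff(self.strains) > 0):
            raise ParameterError("strains must be strictly increasing")
        if np.any(self.stresses < -1e-12):
            raise ParameterError("nominal stress magnitudes must be non-negative")
        if self.strains.size and self.strains[0] == 0.0 and abs(self.stresses[0]) > 1e-9:
            raise ParameterError("stress at zero strain must be zero")

    def __len__(self) -> int:
        return int(self.strains.size)


# ---------------------------------------------------------------------------
# Batched damped Newton on the transverse stretches
# ---------------------------------------------------------------------------

def _residual(C10, D, k1, k2, kappa, theta, l1, l2, la):
    P1, P2, _ = nominal_stress_components(C10, D, k1, k2, kappa, theta, l1, l2, la)
    return P1, P2


def _newton_transverse(C10, D, k1, k2, kappa, theta, la, l1, l2, settings):
    """One equilibrium solve at fixed axial stretch, batched over grids.

    Returns updated (l1, l2, converged_mask).  Entries that fail to reach
    the residual tolerance keep their last iterate and are flagged False.
    """
    tol, max_iter = settings.tol, settings.max_iter
    l1 = np.array(l1, float, copy=True)
    l2 = np.array(l2, float, copy=True)
    active = np.ones(l1.shape, bool)
    h = 1e-7

    for _ in range(max_iter):
        r1, r2 = _residual(C10, D, k1, k2, kappa, theta, l1, l2, la)
        res = np.maximum(np.abs(r1), np.abs(r2))
        res = np.where(np.isfinite(res), res, np.inf)
        active = res > tol
        if not np.any(active):
            break
        # Jacobian of (P1, P2) wrt (l1, l2) by central differences of the
        # analytic stress; accurate enough for quadratic-ish convergence.
        d1 = h * l1
        d2 = h * l2
        a1p, a2p = _residual(C10, D, k1, k2, kappa, theta, l1 + d1, l2, la)
        a1m, a2m = _residual(C10, D, k1, k2, kappa, theta, l1 - d1, l2, la)
        b1p, b2p = _residual(C10, D, k1, k2, kappa, theta, l1, l2 + d2, la)
        b1m, b2m = _residual(C10, D, k1, k2, kappa, theta, l1, l2 - d2, la)
        J11 = (a1p - a1m) / (2.0 * d1)
        J21 = (a2p - a2m) / (2.0 * d1)
        J12 = (b1p - b1m) / (2.0 * d2)
        J22 = (b2p - b2m) / (2.0 * d2)
        det = J11 * J22 - J12 * J21
        safe = np.abs(det) > 1e-300
        det = np.where(safe, det, 1.0)
        s1 = -(J22 * r1 - J12 * r2) / det
        s2 = -(-J21 * r1 + J11 * r2) / det
        s1 = np.where(safe & active & np.isfinite(s1), s1, 0.0)
        s2 = np.where(safe & active & np.isfinite(s2), s2, 0.0)

        # Damped update: backtrack until the residual norm decreases and the
        # trial stretches stay positive.
        step = np.ones_like(l1)
        improved = np.zeros(l1.shape, bool)
        best1, best2 = l1.copy(), l2.copy()
        for _bt in range(12):
            t1 = l1 + step * s1
            t2 = l2 + step * s2
            ok = (t1 > 0.05) & (t2 > 0.05)
            q1, q2 = _residual(C10, D, k1, k2, kappa, theta,
                               np.where(ok, t1, l1), np.where(ok, t2, l2), la)
            qres = np.maximum(np.abs(q1), np.abs(q2))
            qres = np.where(np.isfinite(qres), qres, np.inf)
            better = active & ok & ~improved & (qres < res)
            best1 = np.where(better, t1, best1)
            best2 = np.where(better, t2, best2)
            improved |= better
            if np.all(improved | ~active):
                break
            step = step / 2.0
        l1, l2 = best1, best2
        if not np.any(improved & active):
            break  # stalled everywhere that is still active

    r1, r2 = _residual(C10, D, k1, k2, kappa, theta, l1, l2, la)
    res = np.maximum(np.abs(r1), np.abs(r2))
    converged = np.isfinite(res) & (res <= tol)
    return l1, l2, converged


def _march_axial(C10, D, k1, k2, kappa, theta, lambda_targets, settings):
    """Continuation from the identity to each target axial stretch.

    ``lambda_targets`` must be sorted monotonically away from 1 (all >= 1
    or all <= 1).  Returns (l1, l2, converged) arrays of shape
    (n_targets,) + batch_shape.
    """
    batch = np.broadcast(np.asarray(C10, float), np.asarray(k1, float)).shape
    l1 = np.ones(batch if batch else (1,))
    l2 = np.ones_like(l1)
    alive = np.ones(l1.shape, bool)
    out1, out2, oks = [], [], []

    la_prev = 1.0
    for la_t in lambda_targets:
        n_sub = max(1, int(math.ceil(abs(la_t - la_prev) / settings.max_substep)))
        for j in range(1, n_sub + 1):
            la = la_prev + (la_t - la_prev) * j / n_sub
            l1, l2, conv = _newton_transverse(
                C10, D, k1, k2, kappa, theta, la, l1, l2, settings
            )
            alive &= conv
            # reset dead entries to identity so they cannot poison neighbours
            l1 = np.where(alive, l1, 1.0)
            l2 = np.where(alive, l2, 1.0)
        out1.append(l1.copy())
        out2.append(l2.copy())
        oks.append(alive.copy())
        la_prev = la_t
    return np.array(out1), np.array(out2), np.array(oks)


def solve_uniaxial_state(
    gp: GroundParams,
    fp: FiberParams | None,
    lambda_axial: float,
    settings: SolverSettings | None = None,
) -> tuple[KinematicState, float]:
    """Solve one uniaxial state with traction-free lateral faces.

    Returns the kinematic state at equilibrium and the axial nominal stress
    dU/d(lambda_axial), MPa (signed: negative in compression).

    Raises
    ------
    SolverError
        When the transverse Newton iteration does not reach the residual
        tolerance.
    """
    if not (lambda_axial > 0.0):
        raise ParameterError(f"lambda_axial must be positive, got {lambda_axial}")
    settings = settings or SolverSettings()
    k1 = fp.k1 if fp is not None else 0.0
    k2 = fp.k2 if fp is not None else 1.0
    kappa = fp.kappa if fp is not None else 0.0
    theta = fp.theta_rad if fp is not None else 0.0

    l1, l2, ok = _march_axial(
        np.array([gp.C10]), np.array([gp.D]), np.array([k1]), k2, kappa, theta,
        [lambda_axial], settings,
    )
    if not bool(ok[0, 0]):
        r1, r2 = _residual(gp.C10, gp.D, k1, k2, kappa, theta,
                           l1[0, 0], l2[0, 0], lambda_axial)
        raise SolverError(
            f"transverse equilibrium not reached at lambda={lambda_axial}: "
            f"residuals ({float(r1):.3g}, {float(r2):.3g}) MPa"
        )
    lt1, lt2 = float(l1[0, 0]), float(l2[0, 0])
    _, _, P3 = nominal_stress_components(
        gp.C10, gp.D, k1, k2, kappa, theta, lt1, lt2, lambda_axial
    )
    state = kinematics_uniaxial(lambda_axial, lt1, lt2, fp)
    return state, float(P3)


def simulate_curve_batch(
    C10,
    D,
    k1,
    k2,
    kappa,
    theta_rad,
    strain_levels,
    mode: str,
    settings: SolverSettings | None = None,
):
    """Axial nominal stress magnitudes for a batch of parameter sets.

    All parameter arguments broadcast together over an arbitrary batch
    shape.  Returns (stresses, converged) of shape
    (n_levels,) + batch_shape; failed entries carry ``nan``.
    """
    settings = settings or SolverSettings()
    strain_levels = np.asarray(strain_levels, float)
    if strain_levels.size == 0:
        batch = np.broadcast(np.asarray(C10, float), np.asarray(k1, float)).shape
        return (np.zeros((0,) + batch), np.zeros((0,) + batch, bool))
    sign = -1.0 if mode == "compression" else 1.0
    lambdas = 1.0 + sign * strain_levels
    if np.any(lambdas <= 0.0):
        raise ParameterError("compression strain must be < 1")
    l1, l2, ok = _march_axial(C10, D, k1, k2, kappa, theta_rad, lambdas, settings)
    _, _, P3 = nominal_stress_components(
        C10, D, k1, k2, kappa, theta_rad, l1, l2, lambdas.reshape((-1,) + (1,) * (l1.ndim - 1))
    )
    stress = np.where(ok, np.abs(P3), np.nan)
    return stress, ok


def simulate_compression(
    gp: GroundParams,
    strain_levels=DEFAULT_COMPRESSION_STRAINS,
    fibers: FiberParams | None = None,
    settings: SolverSettings | None = None,
    region: str | None = None,
) -> StressStrainCurve:
    """Uniaxial compression curve of the bare ground substance.

    The compression protocol characterizes the Neo-Hookean matrix alone, so
    no fiber term enters the stress.  If ``fibers`` is supplied the fiber
    strain E_bar is still evaluated at every solved state and
    ``metadata['fiber_activation']`` records whether any state would have
    loaded the fibers (near-incompressibility bulges the transverse faces,
    which can stretch shallow-angle fibers even in axial compression).
    """
    stress, ok = simulate_curve_batch(
        np.array([gp.C10]), np.array([gp.D]), np.array([0.0]), 1.0, 0.0, 0.0,
        strain_levels, "compression", settings,
    )
    if not np.all(ok):
        bad = np.asarray(strain_levels, float)[~ok[:, 0]]
        raise SolverError(f"compression solve failed at strains {bad}")
    meta: dict = {}
    if fibers is not None:
        activated = False
        for eps in np.asarray(strain_levels, float):
            state, _ = solve_uniaxial_state(gp, None, 1.0 - eps, settings)
            ks = kinematics_uniaxial(state.lambda_axial, state.lambda_t1,
                                     state.lambda_t2, fibers)
            if ks.E_bar_a > 0.0 or ks.E_bar_b > 0.0:
                activated = True
        meta["fiber_activation"] = activated
    return StressStrainCurve(
        mode="compression",
        strains=np.asarray(strain_levels, float),
        stresses=stress[:, 0],
        region=region,
        metadata=meta,
    )


def simulate_tension(
    mr: MaterialRegion,
    strain_levels=DEFAULT_TENSION_STRAINS,
    settings: SolverSettings | None = None,
) -> StressStrainCurve:
    """Uniaxial tension curve of a fiber-reinforced annulus region."""
    fp = mr.fibers
    stress, ok = simulate_curve_batch(
        np.array([mr.ground.C10]), np.array([mr.ground.D]),
        np.array([fp.k1]), fp.k2, fp.kappa, fp.theta_rad,
        strain_levels, "tension", settings,
    )
    if not np.all(ok):
        bad = np.asarray(strain_levels, float)[~ok[:, 0]]
        raise SolverError(f"tension solve failed at strains {bad}")
    return StressStrainCurve(
        mode="tension",
        strains=np.asarray(strain_levels, float),
        stresses=stress[:, 0],
        region=mr.region,
    )


def tangent_modulus(curve: StressStrainCurve) -> float:
    """Tangent stiffness, MPa: slope of the final chord of the curve.

    The modulus reported for the tensile specimens is the tangent stiffness
    in the axial direction at the end of the test; here it is the chord
    slope through the last two recorded points.
    """
    if len(curve) < 2:
        raise ParameterError("tangent modulus needs at least two points")
    ds = curve.stresses[-1] - curve.stresses[-2]
    de = curve.strains[-1] - curve.strains[-2]
    return float(ds / de)
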