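"""Holzapfel-Gasser-Ogden (H-G-O) strain energy and parameter conversions.

The annulus fibrosus ground substance is an isotropic, nearly incompressible
Neo-Hookean solid described by ``(C10, D)``; two symmetric families of
collagen fibers add an exponential, tension-only anisotropic term governed by
``(k1, k2, kappa, theta)``.  The strain energy density per unit reference
volume is

    U = C10 (I1_bar - 3) + (1/D) ((J^2 - 1)/2 - ln J)
        + k1/(2 k2) * sum_a { exp(k2 <E_a>^2) - 1 }

with the fiber strain-like quantity

    E_a = kappa (I1_bar - 3) + (1 - 3 kappa) (I4_bar_a - 1)

and the Macaulay bracket ``<x> = max(x, 0)`` implementing the tension-only
switch.  ``I1_bar`` is the first deviatoric invariant, ``J`` the volume
ratio (no swelling split: the elastic volume ratio equals the total one),
and ``I4_bar_a`` the deviatoric pseudo-invariant of fiber family *a*.

Coordinate convention: axis 3 is the specimen load axis (the spine axis);
the fibers lie in the (axis-1, axis-3) plane at +/- theta measured from
axis 1, i.e. from the transverse plane.

Units: stresses and energy densities in MPa; D in MPa^-1; angles in degrees
at the interface (radians internally); strains are engineering strains,
stretches = 1 + strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterError",
    "EnergyOverflowError",
    "ElasticConstants",
    "GroundParams",
    "FiberParams",
    "MaterialRegion",
    "KinematicState",
    "REGIONS",
    "elastic_to_ground",
    "ground_to_elastic",
    "kinematics_uniaxial",
    "strain_energy",
    "nominal_stress_components",
    "fiber_strain",
]

REGIONS = ("anterior", "lateral", "posterior")

#: Largest admissible exponent argument k2 * <E>^2 before the fiber term is
#: treated as a numeric overflow rather than a physical stress.
_EXP_CAP = 700.0


class ParameterError(ValueError):
    """A material or kinematic parameter violates its admissible range."""


class EnergyOverflowError(ArithmeticError):
    """The exponential fiber term is not representable in double precision."""


@dataclass(frozen=True)
class ElasticConstants:
    """Equivalent small-strain elastic constants of the ground substance.

    Attributes
    ----------
    E : float
        Young modulus, MPa.  Must be positive.
    nu : float
        Poisson ratio, dimensionless, in (0, 0.5).  The incompressible
        limit nu = 0.5 is rejected because the inverse bulk parameter D
        would vanish.
    """

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.E > 0.0):
            raise ParameterError(f"Young modulus must be positive, got E={self.E}")
        if not (0.0 < self.nu < 0.5):
            raise ParameterError(f"Poisson ratio must lie in (0, 0.5), got nu={self.nu}")

    @property
    def mu0(self) -> float:
        """Small-strain shear modulus mu0 = E / (2 (1 + nu)), MPa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def K0(self) -> float:
        """Small-strain bulk modulus K0 = E / (3 (1 - 2 nu)), MPa."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class GroundParams:
    """Neo-Hookean ground-substance parameters: C10 (MPa), D (MPa^-1)."""

    C10: float
    D: float

    def __post_init__(self) -> None:
        if not (self.C10 > 0.0):
            raise ParameterError(f"C10 must be positive, got {self.C10}")
        if not (self.D > 0.0):
            raise ParameterError(f"D must be positive, got {self.D}")


@dataclass(frozen=True)
class FiberParams:
    """Exponential fiber-family parameters of the H-G-O energy.

    Attributes
    ----------
    k1 : float
        Fiber stiffness, MPa, >= 0 (k1 = 0 recovers the bare matrix).
    k2 : float
        Fiber non-linearity, dimensionless, > 0.
    kappa : float
        Dispersion in [0, 1/3]; 0 = perfectly aligned, 1/3 = isotropic.
    theta_deg : float
        Fiber angle from the transverse plane, degrees, in [0, 90].
    n_families : int
        Number of fiber families; fixed at 2 (directions at +/- theta).
    """

    k1: float
    k2: float
    kappa: float = 0.01
    theta_deg: float = 30.0
    n_families: int = 2

    def __post_init__(self) -> None:
        if self.k1 < 0.0:
            raise ParameterError(f"k1 must be non-negative, got {self.k1}")
        if not (self.k2 > 0.0):
            raise ParameterError(f"k2 must be positive, got {self.k2}")
        if not (0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12):
            raise ParameterError(f"kappa must lie in [0, 1/3], got {self.kappa}")
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ParameterError(f"theta_deg must lie in [0, 90], got {self.theta_deg}")
        if self.n_families != 2:
            raise ParameterError("exactly two fiber families are supported")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_deg)

    def directions(self) -> np.ndarray:
        """Unit reference directions of the two families, shape (2, 3).

        Both vectors lie in the (axis-1, axis-3) plane at +/- theta from
        axis 1; axis 3 is the load/spine axis.
        """
        c, s = math.cos(self.theta_rad), math.sin(self.theta_rad)
        return np.array([[c, 0.0, s], [c, 0.0, -s]])


@dataclass(frozen=True)
class MaterialRegion:
    """Complete material description of one annulus region."""

    region: str
    ground: GroundParams
    fibers: FiberParams

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ParameterError(
                f"region must be one of {REGIONS}, got {self.region!r}"
            )


@dataclass(frozen=True)
class KinematicState:
    """Invariants of a homogeneous triaxial stretch along the material axes.

    ``I4_bar_*`` and ``E_bar_*`` are ``None`` when the state was built
    without fiber geometry.
    """

    lambda_axial: float
    lambda_t1: float
    lambda_t2: float
    J: float
    I1_bar: float
    I4_bar_a: float | None = None
    I4_bar_b: float | None = None
    E_bar_a: float | None = None
    E_bar_b: float | None = None


# ---------------------------------------------------------------------------
# Parameter conversions
# ---------------------------------------------------------------------------

def elastic_to_ground(ec: ElasticConstants) -> GroundParams:
    """Convert (E, nu) to Neo-Hookean (C10, D).

    C10 = mu0 / 2 = E / (4 (1 + nu));  D = 2 / K0 = 6 (1 - 2 nu) / E.
    Exact inverse of :func:`ground_to_elastic`.
    """
    return GroundParams(C10=ec.mu0 / 2.0, D=2.0 / ec.K0)


def ground_to_elastic(gp: GroundParams) -> ElasticConstants:
    """Convert Neo-Hookean (C10, D) back to (E, nu).

    mu0 = 2 C10, K0 = 2 / D, then the standard isotropic relations
    E = 9 K mu / (3 K + mu), nu = (3 K - 2 mu) / (2 (3 K + mu)).
    The returned nu is always < 0.5 for finite positive D.
    """
    mu0 = 2.0 * gp.C10
    K0 = 2.0 / gp.D
    denom = 3.0 * K0 + mu0
    return ElasticConstants(
        E=9.0 * K0 * mu0 / denom,
        nu=(3.0 * K0 - 2.0 * mu0) / (2.0 * denom),
    )


# ---------------------------------------------------------------------------
# Kinematics and energy
# ---------------------------------------------------------------------------

def _invariants(l1, l2, l3, theta_rad):
    """Deviatoric invariants for diagonal stretch; vectorized over inputs.

    Returns (J, I1_bar, I4_bar) where I4_bar is shared by both families:
    for F = diag(l1, l2, l3) and directions (cos t, 0, +/- sin t) the
    pseudo-invariant a.C_bar.a = J^(-2/3) (l1^2 cos^2 t + l3^2 sin^2 t)
    does not depend on the sign of the axial component.
    """
    J = l1 * l2 * l3
    Jm23 = J ** (-2.0 / 3.0)
    I1_bar = Jm23 * (l1 * l1 + l2 * l2 + l3 * l3)
    c2 = np.cos(theta_rad) ** 2
    s2 = np.sin(theta_rad) ** 2
    I4_bar = Jm23 * (l1 * l1 * c2 + l3 * l3 * s2)
    return J, I1_bar, I4_bar


def fiber_strain(I1_bar, I4_bar, kappa):
    """Strain-like fiber quantity E = kappa (I1_bar - 3) + (1 - 3 kappa)(I4_bar - 1)."""
    return kappa * (I1_bar - 3.0) + (1.0 - 3.0 * kappa) * (I4_bar - 1.0)


def kinematics_uniaxial(
    lambda_axial: float,
    lambda_t1: float,
    lambda_t2: float,
    fibers: FiberParams | None = None,
) -> KinematicState:
    """Kinematic state of a homogeneous stretch diag(l_t1, l_t2, l_axial).

    At the identity: I1_bar = 3, I4_bar = 1, E_bar = 0.
    """
    for name, v in (("lambda_axial", lambda_axial), ("lambda_t1", lambda_t1),
                    ("lambda_t2", lambda_t2)):
        if not (v > 0.0):
            raise ParameterError(f"{name} must be positive, got {v}")
    theta = fibers.theta_rad if fibers is not None else 0.0
    J, I1_bar, I4_bar = _invariants(lambda_t1, lambda_t2, lambda_axial, theta)
    if fibers is None:
        return KinematicState(lambda_axial, lambda_t1, lambda_t2, float(J), float(I1_bar))
    e_bar = fiber_strain(I1_bar, I4_bar, fibers.kappa)
    return KinematicState(
        lambda_axial=lambda_axial,
        lambda_t1=lambda_t1,
        lambda_t2=lambda_t2,
        J=float(J),
        I1_bar=float(I1_bar),
        I4_bar_a=float(I4_bar),
        I4_bar_b=float(I4_bar),
        E_bar_a=float(e_bar),
        E_bar_b=float(e_bar),
    )


def strain_energy(
    gp: GroundParams,
    fp: FiberParams | None,
    ks: KinematicState,
) -> float:
    """H-G-O strain energy density, MPa, at a kinematic state.

    Sum of the deviatoric matrix term, the volumetric term
    (1/D)((J^2 - 1)/2 - ln J), and the tension-only fiber terms: each
    family contributes only when its E_bar is positive.  Zero at the
    identity, strictly positive elsewhere.

    Raises
    ------
    EnergyOverflowError
        When exp(k2 <E>^2) is not finite in double precision.
    """
    u = gp.C10 * (ks.I1_bar - 3.0) + (1.0 / gp.D) * (
        (ks.J * ks.J - 1.0) / 2.0 - math.log(ks.J)
    )
    if fp is not None and fp.k1 > 0.0:
        if ks.E_bar_a is None:
            raise ParameterError("kinematic state carries no fiber invariants")
        for e_bar in (ks.E_bar_a, ks.E_bar_b):
            e_plus = max(e_bar, 0.0)
            arg = fp.k2 * e_plus * e_plus
            if arg > _EXP_CAP:
                raise EnergyOverflowError(
                    f"fiber exponent k2*<E>^2 = {arg:.3g} exceeds double range"
                )
            u += fp.k1 / (2.0 * fp.k2) * (math.exp(arg) - 1.0)
    if not math.isfinite(u):
        raise EnergyOverflowError("strain energy is not finite")
    return u


def nominal_stress_components(C10, D, k1, k2, kappa, theta_rad, l1, l2, l3):
    """Nominal (first Piola-Kirchhoff) stresses on the material axes.

    Analytic partial derivatives (P1, P2, P3) = dU/d(l1, l2, l3) of the
    H-G-O energy for a diagonal stretch state.  All arguments broadcast as
    numpy arrays, so a whole parameter grid is evaluated in one call; pass
    ``k1 = 0`` for a bare Neo-Hookean matrix.  Overflowing fiber
    exponentials propagate as ``inf`` for the caller to detect.
    """
    l1, l2, l3 = np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    J = l1 * l2 * l3
    Jm23 = J ** (-2.0 / 3.0)
    I1 = l1 * l1 + l2 * l2 + l3 * l3
    c2 = np.cos(theta_rad) ** 2
    s2 = np.sin(theta_rad) ** 2
    I4raw = l1 * l1 * c2 + l3 * l3 * s2

    # d(I1_bar)/dli and d(I4_bar)/dli for the deviatoric invariants
    dI1_1 = Jm23 * (2.0 * l1 - (2.0 / 3.0) * I1 / l1)
    dI1_2 = Jm23 * (2.0 * l2 - (2.0 / 3.0) * I1 / l2)
    dI1_3 = Jm23 * (2.0 * l3 - (2.0 / 3.0) * I1 / l3)
    dI4_1 = Jm23 * (2.0 * l1 * c2 - (2.0 / 3.0) * I4raw / l1)
    dI4_2 = Jm23 * (-(2.0 / 3.0) * I4raw / l2)
    dI4_3 = Jm23 * (2.0 * l3 * s2 - (2.0 / 3.0) * I4raw / l3)

    dvol = (1.0 / np.asarray(D, float)) * (J - 1.0 / J)
    P1 = C10 * dI1_1 + dvol * J / l1
    P2 = C10 * dI1_2 + dvol * J / l2
    P3 = C10 * dI1_3 + dvol * J / l3

    k1 = np.asarray(k1, float)
    if np.any(k1 > 0.0):
        e_bar = fiber_strain(Jm23 * I1, Jm23 * I4raw, kappa)
        e_plus = np.maximum(e_bar, 0.0)
        arg = np.minimum(k2 * e_plus * e_plus, _EXP_CAP + 10.0)
        with np.errstate(over="ignore"):
            # factor 2: two identical fiber families for diagonal stretches
            g = 2.0 * k1 * e_plus * np.exp(arg)
        dE_1 = kappa * dI1_1 + (1.0 - 3.0 * kappa) * dI4_1
        dE_2 = kappa * dI1_2 + (1.0 - 3.0 * kappa) * dI4_2
        dE_3 = kappa * dI1_3 + (1.0 - 3.0 * kappa) * dI4_3
        P1 = P1 + g * dE_1
        P2 = P2 + g * dE_2
        P3 = P3 + g * dE_3
    return P1, P2, P3
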