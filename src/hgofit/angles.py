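"""Fiber-angle statistics per annulus region.

Collagen fiber orientations are measured as the angle between the two
fiber families; half of each measured inter-fiber angle is taken as the
orientation with respect to the transverse ("horizontal") plane, so every
measurement lies in (0, 90) degrees.  The per-region summary is the
arithmetic mean and sample standard deviation, backed by a two-standard-
deviation coverage check (under Chebyshev's inequality at least 75% of any
sample, and about 95% of a Gaussian one, lies within two SDs of the mean)
and an omnibus normality test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constitutive import ParameterError

__all__ = [
    "AngleSample",
    "NormalityResult",
    "summarize_angles",
    "two_sd_coverage",
    "normality_check",
]


@dataclass(frozen=True)
class AngleSample:
    """Fiber-angle measurements (degrees from the transverse plane)."""

    region: str
    measurements: tuple

    def __post_init__(self) -> None:
        m = np.asarray(self.measurements, float)
        if m.ndim != 1 or m.size < 1:
            raise ParameterError("measurements must be a non-empty 1-d sequence")
        if np.any(m <= 0.0) or np.any(m >= 90.0):
            raise ParameterError("angle measurements must lie strictly in (0, 90) degrees")
        object.__setattr__(self, "measurements", tuple(float(v) for v in m))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.measurements, float)

    def __len__(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    verdict: str  # "pass" | "fail" | "inconclusive"


def summarize_angles(s: AngleSample) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator), degrees."""
    if len(s) < 2:
        raise ParameterError("angle summary needs at least two measurements")
    a = s.array
    return float(a.mean()), float(a.std(ddof=1))


def two_sd_coverage(s: AngleSample) -> float:
    """Fraction of measurements within [mean - 2 SD, mean + 2 SD].

    A degenerate sample with zero spread has full coverage by definition.
    """
    if len(s) < 3:
        raise ParameterError("coverage needs at least three measurements")
    mean, sd = s.array.mean(), s.array.std(ddof=1)
    if sd == 0.0:
        return 1.0
    within = np.abs(s.array - mean) <= 2.0 * sd
    return float(within.mean())


def normality_check(s: AngleSample, alpha: float = 0.05) -> NormalityResult:
    """D'Agostino-Pearson skewness-kurtosis omnibus normality test.

    Verdict is "pass" when the null of normality is not rejected at level
    ``alpha``, "fail" when it is, and "inconclusive" for samples too small
    (n < 8) or degenerate (zero spread) for the test statistic to exist.
    """
    a = s.array
    if len(s) < 8 or a.std(ddof=1) == 0.0:
        return NormalityResult(float("nan"), float("nan"), "inconclusive")
    stat, p = stats.normaltest(a)
    return NormalityResult(float(stat), float(p),
                           "pass" if p >= alpha else "fail")
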