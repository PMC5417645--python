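"""Full-factorial sensitivity sweep over (E, k1, k2).

A specimen-level surrogate of a disc-level sensitivity study: for every
combination of ground-substance modulus E and fiber parameters (k1, k2)
the virtual tension and compression tests are run and summary outputs
recorded (tensile stresses at the protocol strain levels, final-chord
tangent modulus, compressive stress at 0.30 strain).  The default design
uses four levels per parameter within the studied ranges — E in
[0.1, 1] MPa and k1 in [1, 45] MPa linearly spaced, k2 in [1, 2000]
geometrically spaced since its range spans three orders of magnitude —
for 64 combinations.  The sweep checks the *direction* of each
parameter's influence on specimen stiffness, not disc-level magnitudes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import ParameterError
from .specimen import (
    DEFAULT_TENSION_STRAINS,
    SolverSettings,
    simulate_curve_batch,
)

__all__ = [
    "SensitivityDesign",
    "SensitivityRecord",
    "run_sensitivity",
    "summarize_sensitivity",
    "records_to_dataframe",
]


def _default_levels(name: str) -> tuple:
    if name == "E":
        return tuple(np.linspace(0.1, 1.0, 4))
    if name == "k1":
        return tuple(np.linspace(1.0, 45.0, 4))
    if name == "k2":
        return tuple(np.geomspace(1.0, 2000.0, 4))
    raise ParameterError(name)


@dataclass(frozen=True)
class SensitivityDesign:
    """Levels per parameter of the full-factorial design (default 4 each)."""

    e_levels: tuple = field(default_factory=lambda: _default_levels("E"))
    k1_levels: tuple = field(default_factory=lambda: _default_levels("k1"))
    k2_levels: tuple = field(default_factory=lambda: _default_levels("k2"))

    def __post_init__(self) -> None:
        for name, lv in (("E", self.e_levels), ("k1", self.k1_levels),
                         ("k2", self.k2_levels)):
            arr = np.asarray(lv, float)
            if arr.size < 1:
                raise ParameterError(f"{name} needs at least one level")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ParameterError(f"{name} levels must be strictly increasing")
            object.__setattr__(self, {"E": "e_levels", "k1": "k1_levels",
                                      "k2": "k2_levels"}[name],
                               tuple(float(v) for v in arr))

    @property
    def n_combinations(self) -> int:
        return len(self.e_levels) * len(self.k1_levels) * len(self.k2_levels)


@dataclass(frozen=True)
class SensitivityRecord:
    """Specimen-level outputs for one (E, k1, k2) combination."""

    E: float
    k1: float
    k2: float
    tension_strains: tuple
    tension_stresses: tuple  # MPa, nan entries on solver failure
    tangent_modulus: float  # MPa, final chord of the tension curve
    compression_stress_030: float  # MPa at 0.30 compressive strain
    failed: bool = False


def run_sensitivity(
    design: SensitivityDesign | None = None,
    theta_deg: float = 29.0,
    nu: float = 0.49,
    kappa: float = 0.01,
    strain_levels=DEFAULT_TENSION_STRAINS,
    settings: SolverSettings | None = None,
) -> list[SensitivityRecord]:
    """Evaluate every (E, k1, k2) combination; deterministic, exhaustive.

    Records are ordered lexicographically by (E, k1, k2).  A solver
    failure at one point marks that record failed and the sweep continues.
    """
    design = design or SensitivityDesign()
    ev = np.asarray(design.e_levels)
    k1v = np.asarray(design.k1_levels)
    k2v = np.asarray(design.k2_levels)
    E, K1, K2 = np.meshgrid(ev, k1v, k2v, indexing="ij")
    c10 = E / (4.0 * (1.0 + nu))
    d = 6.0 * (1.0 - 2.0 * nu) / E
    strain_levels = np.asarray(strain_levels, float)

    tens, ok_t = simulate_curve_batch(
        c10, d, K1, K2, kappa, np.radians(theta_deg),
        strain_levels, "tension", settings,
    )
    comp, ok_c = simulate_curve_batch(
        c10, d, np.zeros_like(K1), 1.0, 0.0, 0.0,
        [0.30], "compression", settings,
    )

    records: list[SensitivityRecord] = []
    for idx in itertools.product(range(ev.size), range(k1v.size), range(k2v.size)):
        i, j, k = idx
        ts = tens[(slice(None),) + idx]
        ok = bool(np.all(ok_t[(slice(None),) + idx])) and bool(ok_c[(0,) + idx])
        if len(ts) >= 2 and np.isfinite(ts[-1]) and np.isfinite(ts[-2]):
            tan = float((ts[-1] - ts[-2]) / (strain_levels[-1] - strain_levels[-2]))
        else:
            tan = float("nan")
        records.append(SensitivityRecord(
            E=float(ev[i]), k1=float(k1v[j]), k2=float(k2v[k]),
            tension_strains=tuple(strain_levels),
            tension_stresses=tuple(float(v) for v in ts),
            tangent_modulus=tan,
            compression_stress_030=float(comp[(0,) + idx]),
            failed=not ok,
        ))
    return records


def records_to_dataframe(records: list[SensitivityRecord]) -> pd.DataFrame:
    """Flatten records to one row per combination for CSV export."""
    rows = []
    for r in records:
        row = {"E": r.E, "k1": r.k1, "k2": r.k2}
        for eps, s in zip(r.tension_strains, r.tension_stresses):
            row[f"tension_stress_{eps:.2f}"] = s
        row["tangent_modulus"] = r.tangent_modulus
        row["compression_stress_0.30"] = r.compression_stress_030
        row["failed"] = r.failed
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_sensitivity(records: list[SensitivityRecord]) -> dict:
    """Per-parameter-level quartile summaries suitable for box plots.

    For each parameter (E, k1, k2) and each of its levels, the quartiles
    (min, q1, median, q3, max) of every output over all combinations of
    the other parameters.  Levels whose records all failed are reported
    as ``None``.
    """
    if not records:
        raise ParameterError("no records to summarize")
    df = records_to_dataframe(records)
    outputs = [c for c in df.columns if c not in ("E", "k1", "k2", "failed")]
    summary: dict = {}
    for param in ("E", "k1", "k2"):
        summary[param] = {}
        for level, grp in df.groupby(param, sort=True):
            good = grp[~grp["failed"]]
            entry = {}
            for out in outputs:
                vals = good[out].to_numpy()
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    entry[out] = None
                else:
                    q = np.percentile(vals, [0, 25, 50, 75, 100])
                    entry[out] = {
                        "min": float(q[0]), "q1": float(q[1]),
                        "median": float(q[2]), "q3": float(q[3]),
                        "max": float(q[4]),
                    }
            summary[param][float(level)] = entry
    return summary
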