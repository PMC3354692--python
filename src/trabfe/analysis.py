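"""Relative-modulus curves and regression analysis.

The study quantity is the *relative modulus* RE(d) = E_app(method, d) /
E_app(basic), the apparent modulus of a coarsened model normalised by the
basic 36 µm model of the same specimen. Two fit forms are provided, both
used in the source analysis: ordinary least squares linear in d, and
logarithmic (RE = a·ln d + b) restricted to voxel lengths d ≤ 300 µm.
Finally, per-specimen log-fit slopes are regressed against the structural
indices (BV/TV, Tb.Th, Tb.N, V_m) — one regression per (method, index)
cell. The magnitude |a| is the dependent variable (steeper decay = larger
|a|); both the raw fitted slope and its magnitude are reported so either
sign convention is inspectable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .fesolve import LoadCase, MaterialProps, compute_apparent_modulus
from .io_stack import ImageStack
from .model_build import build_basic_model, coarsen

__all__ = [
    "RelativeModulusCurve",
    "RegressionResult",
    "relative_modulus_curve",
    "linear_fit",
    "log_fit",
    "slope_index_table",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ("bv_tv", "tb_th", "tb_n", "v_m")
BASIC_D_UM = 36.0
LOG_FIT_D_MAX_UM = 300.0


@dataclass
class RelativeModulusCurve:
    sample_id: str
    method: str
    d_um: np.ndarray          # voxel lengths, µm (starts at 36 = basic)
    relative_e: np.ndarray    # E_app(d) / E_app(basic)
    e_app_gpa: np.ndarray     # absolute moduli, GPa
    basic_modulus_gpa: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_id, "method": self.method,
            "d_um": self.d_um, "e_app_gpa": self.e_app_gpa,
            "relative_e": self.relative_e,
        })


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    form: str = "linear"      # "linear" (in d) or "log" (in ln d)
    n_points: int = field(default=0)


def relative_modulus_curve(sample: ImageStack, method: str, d_values,
                           sample_id: str = "sample",
                           mat: MaterialProps = MaterialProps(),
                           load: LoadCase = LoadCase(),
                           solver: str = "auto", tol: float = 1e-8,
                           basic_modulus: float | None = None,
                           enforce_range: bool = True) -> RelativeModulusCurve:
    """RE(d) for one specimen and one coarsening method.

    Recomputes the basic modulus unless one is supplied (cohort runs reuse
    it across the four methods). The basic point (d = 36 µm, RE = 1) is
    included in the curve.
    """
    if basic_modulus is None:
        basic_modulus = compute_apparent_modulus(
            build_basic_model(sample), mat, load, solver=solver, tol=tol)
    if basic_modulus <= 0:
        raise AnalysisError(f"basic model of {sample_id!r} has zero modulus")
    d_sorted = sorted(float(d) for d in d_values)
    e_apps = [basic_modulus]
    for d in d_sorted:
        model = coarsen(sample, method, d, enforce_range=enforce_range)
        e_apps.append(compute_apparent_modulus(model, mat, load,
                                               solver=solver, tol=tol))
    d_all = np.array([BASIC_D_UM] + d_sorted)
    e_all = np.array(e_apps)
    return RelativeModulusCurve(sample_id, method, d_all, e_all / basic_modulus,
                                e_all, basic_modulus)


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares y = a·x + b with R².

    Constant x is rejected; constant y returns a = 0 with R² = 0 by the
    documented zero-variance convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("x is constant; slope undefined")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    a = sxy / sxx
    b = float(y.mean()) - a * float(x.mean())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        r2 = 0.0
    else:
        resid = y - (a * x + b)
        r2 = 1.0 - float((resid**2).sum()) / sst
    return RegressionResult(a, b, r2, form="linear", n_points=x.size)


def log_fit(d_values, re_values, d_max: float = LOG_FIT_D_MAX_UM) -> RegressionResult:
    """Least-squares RE = a·ln(d) + b over points with d ≤ ``d_max`` (µm)."""
    d = np.asarray(d_values, float)
    re = np.asarray(re_values, float)
    keep = d <= d_max
    if keep.sum() < 3:
        raise ValueError(f"fewer than 3 points with d <= {d_max} µm")
    res = linear_fit(np.log(d[keep]), re[keep])
    return RegressionResult(res.slope, res.intercept, res.r2, form="log",
                            n_points=res.n_points)


def slope_index_table(samples: pd.DataFrame, methods=None) -> pd.DataFrame:
    """Per-(method, index) regression of log-fit slope magnitude on the index.

    ``samples`` holds one row per (sample_id, method) with columns ``a``
    (the log-fit slope of that sample's RE curve) and the four structural
    indices of the *basic* model. Returns one row per (method, index) with
    the fitted slope ``a`` (raw sign), ``abs_a``, intercept ``b`` and ``r2``.
    Invariant under sample-order permutation.
    """
    required = {"sample_id", "method", "a", *INDEX_COLUMNS}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns {sorted(missing)}")
    if methods is None:
        methods = sorted(samples["method"].unique())
    rows = []
    for method in methods:
        sub = samples[samples["method"] == method].sort_values("sample_id")
        if len(sub) < 3:
            raise ValueError(f"need >= 3 samples per method, got {len(sub)} "
                             f"for {method}")
        abs_a = np.abs(sub["a"].to_numpy(float))
        for index in INDEX_COLUMNS:
            fit = linear_fit(sub[index].to_numpy(float), abs_a)
            rows.append({"method": method, "index": index,
                         "a": fit.slope, "abs_a": abs(fit.slope),
                         "b": fit.intercept, "r2": fit.r2, "n": fit.n_points})
    return pd.DataFrame(rows)
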