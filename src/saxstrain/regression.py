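"""Group-level strain-slope regression, slope comparison, and the slope sum.

The central quantity is the regression slope of material strain (collagen or
mineral, from Bragg-peak shifts) on bulk tissue strain: the fraction of the
applied tissue deformation carried by that phase.  Points from all specimens
of a group are pooled into one scatter and fit by ordinary least squares.

Two groups' slopes are compared with the extra sum-of-squares F test between
a common-slope model (separate intercepts, one shared slope) and a
separate-slopes model.  The hypothesis concerns the slopes only, so the
intercepts remain free in both models.

The slope-sum diagnostic adds a group's collagen and mineral slopes: a sum
near 1 means the two observed phases account for the whole tissue strain (a
stable composite); a deficit indicates unobserved strain pathways such as
fibril sliding.  Because collagen and mineral are typically measured on
contralateral limbs, the diagnostic carries a caveat flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pairing import PairedStrainSeries

__all__ = [
    "SlopeFit",
    "FTestResult",
    "CompositeDiagnostic",
    "fit_group_slope",
    "compare_slopes",
    "slope_sum",
]


@dataclass
class SlopeFit:
    """Pooled OLS fit of material strain on tissue strain for one group."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    n_points: int
    n_samples: int
    r_squared: float
    group: tuple = ()
    phase: str = ""

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        t_crit = stats.t.ppf(0.5 + level / 2.0, df=self.n_points - 2)
        return (self.slope - t_crit * self.slope_se, self.slope + t_crit * self.slope_se)


def _pool(points) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack (tissue, material) strain pairs from series, frames, or arrays."""
    if isinstance(points, PairedStrainSeries):
        points = [points]
    if isinstance(points, pd.DataFrame):
        x = points["tissue_strain"].to_numpy(dtype=float)
        y = points["material_strain"].to_numpy(dtype=float)
        n_samples = points["sample_id"].nunique() if "sample_id" in points else 1
    else:
        items = list(points)
        if items and all(isinstance(p, PairedStrainSeries) for p in items):
            x = np.concatenate([p.tissue_strain for p in items])
            y = np.concatenate([p.material_strain for p in items])
            n_samples = len(items)
        else:
            x, y = (np.asarray(v, dtype=float) for v in items)
            n_samples = 1
    good = np.isfinite(x) & np.isfinite(y)
    return x[good], y[good], n_samples


def fit_group_slope(
    points,
    group: tuple = (),
    phase: str = "",
) -> SlopeFit:
    """OLS of pooled material strain on tissue strain; SE from residuals.

    ``points`` may be one ``PairedStrainSeries``, a list of them (one per
    specimen, pooled), a DataFrame with ``tissue_strain``/``material_strain``
    columns, or an ``(x, y)`` pair of arrays.
    """
    x, y, n_samples = _pool(points)
    if x.size < 3:
        raise ValueError("need at least 3 points to fit a group slope")
    if np.ptp(x) == 0:
        raise ValueError("tissue strain has zero variance; slope is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SlopeFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        n_points=int(x.size),
        n_samples=n_samples,
        r_squared=float(res.rsquared),
        group=tuple(group),
        phase=phase,
    )


@dataclass
class FTestResult:
    """Extra sum-of-squares F test for equality of two regression slopes."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    sse_common: float
    sse_separate: float
    null_model: str = "common-slope"
    alt_model: str = "separate-slopes"

    def significant(self, alpha: float = 0.0125) -> bool:
        return self.p_value < alpha


def compare_slopes(points_a, points_b) -> FTestResult:
    """Test slope equality between two pooled scatters.

    F = ((SSE_common - SSE_separate) / 1) / (SSE_separate / (n - 4)), where
    the common model fits separate intercepts and one shared slope and the
    separate model adds a per-group slope.  Two noiseless lines of different
    slope give SSE_separate = 0; that limit is reported as F = inf, p = 0.
    """
    xa, ya, _ = _pool(points_a)
    xb, yb, _ = _pool(points_b)
    for x, name in ((xa, "A"), (xb, "B")):
        if x.size < 3 or np.ptp(x) == 0:
            raise ValueError(f"group {name} is degenerate: cannot fit its own slope")
    n = xa.size + xb.size
    y = np.concatenate([ya, yb])
    ind_a = np.concatenate([np.ones(xa.size), np.zeros(xb.size)])
    ind_b = 1.0 - ind_a
    x = np.concatenate([xa, xb])
    design_common = np.column_stack([ind_a, ind_b, x])
    design_separate = np.column_stack([ind_a, ind_b, x * ind_a, x * ind_b])

    def sse(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r)

    sse_c, sse_s = sse(design_common), sse(design_separate)
    df_den = n - 4
    if df_den < 1:
        raise ValueError("too few points for the separate-slopes model")
    scale = max(sse_c, 1e-300)
    if sse_s / scale < 1e-12 and sse_c - sse_s > 0:
        return FTestResult(np.inf, 1, df_den, 0.0, sse_c, sse_s)
    f_stat = max((sse_c - sse_s), 0.0) / (sse_s / df_den)
    p = float(stats.f.sf(f_stat, 1, df_den))
    return FTestResult(float(f_stat), 1, df_den, p, sse_c, sse_s)


@dataclass
class CompositeDiagnostic:
    """Collagen slope + mineral slope with propagated SE and classification.

    ``balanced`` when the 2-SE interval covers 1, ``deficient`` when the sum
    is below 1 beyond 2 SE (unaccounted deformation, e.g. fibril sliding),
    ``oversumming`` when above beyond 2 SE.
    """

    slope_sum: float
    se_sum: float
    classification: str
    group: tuple = ()
    contralateral_caveat: bool = True

    def __post_init__(self) -> None:
        expected = _classify(self.slope_sum, self.se_sum)
        if self.classification != expected:
            raise ValueError("classification inconsistent with slope sum thresholds")


def _classify(total: float, se: float) -> str:
    if total + 2.0 * se < 1.0:
        return "deficient"
    if total - 2.0 * se > 1.0:
        return "oversumming"
    return "balanced"


def slope_sum(collagen: SlopeFit, mineral: SlopeFit) -> CompositeDiagnostic:
    """Sum the collagen and mineral slope fits of one group."""
    if collagen.group != mineral.group:
        raise ValueError(
            f"slope sum requires matching groups, got {collagen.group} vs {mineral.group}"
        )
    if {collagen.phase, mineral.phase} != {"collagen", "mineral"}:
        raise ValueError("slope sum requires one collagen fit and one mineral fit")
    total = collagen.slope + mineral.slope
    se = float(np.hypot(collagen.slope_se, mineral.slope_se))
    return CompositeDiagnostic(total, se, _classify(total, se), group=collagen.group)
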