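"""Factorial ANOVA, Fisher's LSD post hocs, and Bonferroni alpha families.

Outcome tables are long-format DataFrames with factor columns (``age``,
``genotype``, optionally ``sex``) and a numeric ``value`` column.  Two-way
fixed-effects ANOVA with interaction uses Type I sums of squares on balanced
designs (where all types coincide) and Type II on unbalanced ones.  Simple
pairwise effects are then tested with Fisher's least significant difference
using the ANOVA residual mean square, at alpha levels Bonferroni-corrected
for the a-priori comparison family (e.g. 0.05 / 4 = 0.0125 for a 4-way
family, printed 0.007 for a 7-way family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "CorrectedAlpha",
    "two_way_anova",
    "one_way_anova",
    "fisher_lsd",
    "bonferroni_alpha",
]


@dataclass
class AnovaTable:
    """Per-term (SS, df, MS, F, p) decomposition plus fit bookkeeping."""

    table: pd.DataFrame  # index: term names + "residual"; columns ss, df, ms, f, p
    factors: tuple[str, ...]
    response: str
    ss_type: int
    data: pd.DataFrame

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["residual", "df"])

    @property
    def mse(self) -> float:
        return float(self.table.loc["residual", "ms"])


def _check_cells(data: pd.DataFrame, factors, response: str, min_obs: int = 2):
    levels = [sorted(data[f].unique()) for f in factors]
    if any(len(lv) < 2 for lv in levels):
        raise ValueError("every tested factor needs at least 2 levels")
    if data[response].isna().any() or any(data[f].isna().any() for f in factors):
        raise ValueError("missing factor labels or response values")
    counts = data.groupby(list(factors), observed=True)[response].count()
    full = pd.MultiIndex.from_product(levels, names=list(factors)) if len(factors) > 1 \
        else pd.Index(levels[0], name=factors[0])
    for cell in full:
        n = counts.get(cell, 0)
        if n < min_obs:
            raise ValueError(f"cell {cell} has {n} observations; need >= {min_obs}")
    return counts


def _tidy(anova_lm: pd.DataFrame, factors) -> pd.DataFrame:
    rename = {f"C({f})": f for f in factors}
    if len(factors) == 2:
        rename[f"C({factors[0]}):C({factors[1]})"] = f"{factors[0]}:{factors[1]}"
    rename["Residual"] = "residual"
    out = anova_lm.rename(index=rename)
    out = out.rename(columns={"sum_sq": "ss", "F": "f", "PR(>F)": "p"})
    out["ms"] = out["ss"] / out["df"]
    return out[["ss", "df", "ms", "f", "p"]]


def two_way_anova(
    data: pd.DataFrame,
    factors: tuple[str, str] = ("age", "genotype"),
    response: str = "value",
) -> AnovaTable:
    """Fixed-effects two-way ANOVA with interaction.

    Balanced designs use Type I sums of squares (identical to Types II/III
    there); unbalanced designs use Type II.  An empty or underpopulated cell
    raises an error naming the cell.
    """
    counts = _check_cells(data, factors, response, min_obs=2)
    balanced = counts.nunique() == 1
    a, b = factors
    model = smf.ols(f"{response} ~ C({a}) * C({b})", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 F ratios on degenerate data
        table = sm.stats.anova_lm(model, typ=1 if balanced else 2)
    return AnovaTable(_tidy(table, factors), factors, response, 1 if balanced else 2, data)


def one_way_anova(
    data: pd.DataFrame,
    factor: str = "age",
    response: str = "value",
) -> AnovaTable:
    """Standard one-way decomposition; needs >= 2 groups of >= 2 observations."""
    _check_cells(data, (factor,), response, min_obs=2)
    model = smf.ols(f"{response} ~ C({factor})", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=1)
    return AnovaTable(_tidy(table, (factor,)), (factor,), response, 1, data)


class LsdResult(NamedTuple):
    t_statistic: float
    df: float
    p_value: float
    mean_difference: float


def fisher_lsd(anova: AnovaTable, cell_a, cell_b) -> LsdResult:
    """Fisher's LSD test between two design cells after an ANOVA.

    ``t = (mean_a - mean_b) / sqrt(MSE (1/n_a + 1/n_b))`` on the ANOVA
    residual degrees of freedom; two-sided p.  Cells are tuples of factor
    levels in the ANOVA's factor order (a bare level for a one-way table).
    """
    data = anova.data

    def cell_values(cell):
        levels = (cell,) if np.isscalar(cell) or isinstance(cell, str) else tuple(cell)
        if len(levels) != len(anova.factors):
            raise ValueError(f"cell {cell!r} does not match factors {anova.factors}")
        mask = np.ones(len(data), dtype=bool)
        for f, lv in zip(anova.factors, levels):
            mask &= (data[f] == lv).to_numpy()
        if not mask.any():
            raise ValueError(f"cell {cell!r} is not present in the design")
        return data.loc[mask, anova.response].to_numpy(dtype=float)

    va, vb = cell_values(cell_a), cell_values(cell_b)
    diff = float(va.mean() - vb.mean())
    se = float(np.sqrt(anova.mse * (1.0 / len(va) + 1.0 / len(vb))))
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), anova.residual_df)) if np.isfinite(t) else 0.0
    return LsdResult(float(t), anova.residual_df, min(p, 1.0), diff)


class CorrectedAlpha(NamedTuple):
    exact: float
    printed: float  # round-half-even to 3 decimals (reporting convention)
    m: int
    family_alpha: float


def bonferroni_alpha(m: int, family_alpha: float = 0.05) -> CorrectedAlpha:
    """A-priori Bonferroni-corrected per-comparison alpha for an m-way family.

    ``alpha_c = family_alpha / m``; the value is reported both exact and
    rounded half-even to 3 decimals (m=4 -> 0.0125; m=6 -> 0.008;
    m=7 -> 0.007).
    """
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError("the comparison family must contain at least 1 comparison")
    if not 0 < family_alpha < 1:
        raise ValueError("family alpha must lie in (0, 1)")
    exact = family_alpha / m
    return CorrectedAlpha(exact, round(exact, 3), int(m), family_alpha)
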