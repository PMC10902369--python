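"""Statistical comparison of IST and CT heterogeneity indices.

Summary statistics (population-SD convention), the Pearson correlation
matrix with two-sided p-values, per-animal and pooled ordinary
least-squares regressions, and the four-quadrant trend-concordance
analysis of paired PEEP-induced changes with a 15%-of-maximum exclusion
zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "summary_stats",
    "round_half_up",
    "pearson_matrix",
    "per_animal_regression",
    "delta_pairs",
    "four_quadrant",
    "QuadrantAnalysis",
]


def summary_stats(values) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (divide by n).

    The population-SD convention matches how cohort baseline tables in this
    field are usually printed (and is what the tests check against known
    printed values).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    return float(v.mean()), float(v.std(ddof=0))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to a stated number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pearson_matrix(
    table: pd.DataFrame,
    variables: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r matrix and two-sided p-value matrix.

    Entries with fewer than 3 complete pairs or zero variance are NaN.
    """
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            if j < i:
                continue
            if i == j:
                xi = table[vi].dropna().to_numpy(float)
                if len(xi) >= 3 and np.std(xi) > 0:
                    r[i, i], p[i, i] = 1.0, 0.0
                continue
            sub = table[[vi, vj]].dropna()
            if len(sub) < 3:
                continue
            xi, xj = sub[vi].to_numpy(float), sub[vj].to_numpy(float)
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            res = sps.pearsonr(xi, xj)
            r[i, j] = r[j, i] = float(np.asarray(res.statistic).item())
            p[i, j] = p[j, i] = float(np.asarray(res.pvalue).item())
    return (
        pd.DataFrame(r, index=variables, columns=variables),
        pd.DataFrame(p, index=variables, columns=variables),
    )


def per_animal_regression(
    table: pd.DataFrame,
    x: str = "h_ct",
    y: str = "log_sd_v",
    animal_col: str = "animal",
) -> pd.DataFrame:
    """Ordinary least-squares y ~ x per animal, plus a pooled 'overall' row.

    Returns a frame with columns (animal, slope, intercept, r2, n); animals
    with fewer than 3 complete points, or a degenerate x, get NaN results.
    """
    rows = []
    groups = [(str(a), g) for a, g in table.groupby(animal_col)]
    groups.append(("overall", table))
    for label, g in groups:
        sub = g[[x, y]].dropna()
        if len(sub) < 3 or np.std(sub[x].to_numpy(float)) == 0:
            rows.append(
                {"animal": label, "slope": np.nan, "intercept": np.nan,
                 "r2": np.nan, "n": len(sub)}
            )
            continue
        res = sps.linregress(sub[x], sub[y])
        rows.append(
            {
                "animal": label,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def delta_pairs(
    table: pd.DataFrame,
    x: str = "h_ct",
    y: str = "log_sd_v",
    animal_col: str = "animal",
    step_col: str = "step",
) -> pd.DataFrame:
    """Paired per-step changes (delta x, delta y) along the PEEP ladder.

    Repeated measurements at the same protocol step are averaged first;
    each animal then contributes one pair per consecutive step (6 pairs on
    the 7-step ladder).  Steps missing either variable are skipped.
    """
    per_step = (
        table.groupby([animal_col, step_col])[[x, y]].mean().reset_index()
    )
    rows = []
    for a, g in per_step.groupby(animal_col):
        g = g.sort_values(step_col)
        steps = g[step_col].to_numpy()
        xv = g[x].to_numpy(float)
        yv = g[y].to_numpy(float)
        for i in range(1, len(g)):
            if steps[i] != steps[i - 1] + 1:
                continue
            dx, dy = xv[i] - xv[i - 1], yv[i] - yv[i - 1]
            if math.isnan(dx) or math.isnan(dy):
                continue
            rows.append({"animal": a, "step": int(steps[i]), "dx": dx, "dy": dy})
    return pd.DataFrame(rows, columns=["animal", "step", "dx", "dy"])


@dataclass
class QuadrantAnalysis:
    """Four-quadrant trend-agreement summary of paired changes."""

    pairs: pd.DataFrame
    exclusion_frac: float
    concordance: float  # percent of included pairs with same-sign changes
    slope: float
    r_squared: float
    n_excluded: int
    n_included: int

    def __post_init__(self) -> None:
        if not math.isnan(self.concordance) and not (0 <= self.concordance <= 100):
            raise ValueError("concordance must be a percentage")


def four_quadrant(
    pairs: pd.DataFrame,
    exclusion_frac: float = 0.15,
) -> QuadrantAnalysis:
    """Four-quadrant concordance of paired changes.

    The exclusion zone is the axis-aligned rectangle
    ``|dx| < exclusion_frac * max|dx|`` AND ``|dy| < exclusion_frac * max|dy|``
    (15% of the maximum observed change on each axis by default).  The
    concordance rate is the percentage of non-excluded pairs in quadrants
    I (+;+) and III (-;-); pairs exactly on an axis count as discordant.
    Slope and R^2 come from OLS over *all* pairs.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    dx = pairs["dx"].to_numpy(float)
    dy = pairs["dy"].to_numpy(float)
    mx, my = np.max(np.abs(dx)), np.max(np.abs(dy))
    excluded = (np.abs(dx) < exclusion_frac * mx) & (np.abs(dy) < exclusion_frac * my)
    included = ~excluded
    n_inc = int(included.sum())
    if n_inc == 0:
        concordance = float("nan")
    else:
        concordance = 100.0 * float((dx[included] * dy[included] > 0).sum()) / n_inc
    if len(pairs) >= 3 and np.std(dx) > 0:
        res = sps.linregress(dx, dy)
        slope, r2 = float(res.slope), float(res.rvalue**2)
    else:
        slope, r2 = float("nan"), float("nan")
    return QuadrantAnalysis(
        pairs=pairs,
        exclusion_frac=exclusion_frac,
        concordance=concordance,
        slope=slope,
        r_squared=r2,
        n_excluded=int(excluded.sum()),
        n_included=n_inc,
    )
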