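"""Administrative population-structure descriptors.

A country's internal administrative geography is summarised by two numbers:
the Gini coefficient of its region population sizes (how unequally the
national population is spread over regions) and the mean region size in
millions of inhabitants.  The Gini coefficient is obtained from the Lorenz
curve — the cumulative share of population held by the smallest k regions
plotted against k/n — as twice the area between that curve and the 1:1
equality diagonal, evaluated in closed form by the trapezoid (Brown) rule.

These descriptors are the country-level covariates of the variance-function
models in :mod:`geostruct.model`, and their mutual association is assessed
with a weighted Pearson correlation (weights = number of regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedCorrelationError

__all__ = [
    "LorenzCurve",
    "lorenz_curve",
    "gini_brown",
    "gini",
    "mean_region_size",
    "weighted_pearson",
    "country_structure_table",
]


@dataclass(frozen=True)
class LorenzCurve:
    """Lorenz coordinates for one country's region population sizes.

    ``x[k]`` is the cumulative proportion of regions after the k-th
    smallest region, ``y[k]`` the cumulative proportion of the national
    population those regions hold.  The implicit origin (0, 0) is not
    stored; area computations prepend it.
    """

    x: np.ndarray
    y: np.ndarray

    def with_origin(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates including the leading (0, 0) vertex."""
        return np.concatenate([[0.0], self.x]), np.concatenate([[0.0], self.y])


def lorenz_curve(populations) -> LorenzCurve:
    """Build the Lorenz curve of a set of region population sizes.

    Sizes are ranked ascending (the standard convention, which keeps the
    curve below the diagonal); ties are left in input order, which cannot
    affect the curve.
    """
    pops = np.asarray(populations, dtype=float)
    if pops.ndim != 1 or pops.size < 1:
        raise DomainError("need a one-dimensional, non-empty list of sizes")
    if np.any(pops <= 0) or not np.all(np.isfinite(pops)):
        raise DomainError("all region populations must be positive and finite")
    ranked = np.sort(pops, kind="stable")
    n = ranked.size
    x = np.arange(1, n + 1) / n
    y = np.cumsum(ranked) / ranked.sum()
    return LorenzCurve(x=x, y=y)


def gini_brown(curve: LorenzCurve | "np.ndarray | list") -> float:
    """Gini coefficient by Brown's trapezoid formula.

    G = \\|1 − Σ_k (x_k − x_{k−1})(y_k + y_{k−1})\\| with (x_0, y_0) = (0, 0),
    i.e. twice the area between the Lorenz polyline and the equality
    diagonal.  Accepts either a :class:`LorenzCurve` or raw sizes.
    """
    if not isinstance(curve, LorenzCurve):
        curve = lorenz_curve(curve)
    x, y = curve.with_origin()
    g = 1.0 - float(np.sum(np.diff(x) * (y[1:] + y[:-1])))
    return abs(g)


def gini(populations) -> float:
    """Convenience wrapper: Brown-method Gini straight from sizes."""
    return gini_brown(lorenz_curve(populations))


def mean_region_size(populations) -> float:
    """Arithmetic mean region population, in millions of inhabitants."""
    pops = np.asarray(populations, dtype=float)
    if pops.size < 1:
        raise DomainError("need at least one region")
    return float(pops.mean()) / 1e6


def weighted_pearson(x, y, w) -> tuple[float, float]:
    """Weighted Pearson correlation with a two-sided t-test p-value.

    Weighted means, variances and covariance all use the same weights; the
    significance test uses ``t = r sqrt((n-2)/(1-r^2))`` on ``n - 2``
    degrees of freedom where n is the number of pairs — the weights rescale
    the moments, not the sample size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise DomainError("x, y, w must be one-dimensional and equally long")
    n = x.size
    if n < 3:
        raise DomainError("need at least 3 pairs for a correlation test")
    if np.any(w <= 0):
        raise DomainError("weights must be positive")
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    dx, dy = x - mx, y - my
    vx = np.sum(w * dx * dx) / sw
    vy = np.sum(w * dy * dy) / sw
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("zero weighted variance in x or y")
    r = float(np.sum(w * dx * dy) / sw / np.sqrt(vx * vy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def country_structure_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-country structure descriptors from a region–age count table.

    Region populations are summed over age bands first; the returned frame
    mirrors a country-summary table: one row per country with the region
    count, mean/min/max region population, mean size in millions and the
    Gini coefficient.
    """
    region_pop = (
        table.groupby(["country_id", "region_id"], sort=False)["population"]
        .sum()
    )
    rows = []
    for cid, pops in region_pop.groupby(level=0, sort=False):
        p = pops.to_numpy(dtype=float)
        rows.append(
            {
                "country_id": cid,
                "n_regions": p.size,
                "mean_pop": float(p.mean()),
                "mean_pop_millions": mean_region_size(p),
                "min_pop": float(p.min()),
                "max_pop": float(p.max()),
                "gini": gini(p),
            }
        )
    return pd.DataFrame(rows)
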