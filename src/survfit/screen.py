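"""Screening for genes with large fitness values or fitness changes.

Along a condition gradient (incubation time, pH, or glucose concentration)
a gene is called a hit when the fitness change between the two endpoint
conditions is large (|delta| at or above a cutoff, 1.5 log2 units by
default) AND the gene's fitness trajectory over the whole gradient is well
described by a second-order polynomial (R^2 >= 0.50 by default), which
filters out erratic single-point excursions.  For single-condition screens
only the magnitude threshold applies, to the fitness values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GradientSeries",
    "ScreenConfig",
    "delta_fitness",
    "threshold_hits",
    "quadratic_r2",
    "screen_gradient",
    "screen_values",
]

_EPS = 1e-12


@dataclass
class GradientSeries:
    """Per-gene fitness vectors aligned to an ordered condition gradient."""

    axis: str
    values: list[float]
    fitness: pd.DataFrame  # genes x conditions, columns aligned to values

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("a gradient needs at least 2 conditions")
        diffs = np.diff(self.values)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("condition values must be strictly monotone")
        if self.fitness.shape[1] != len(self.values):
            raise ValueError("fitness columns do not match condition values")


@dataclass
class ScreenConfig:
    cutoff: float = 1.5
    r2_min: float = 0.50
    direction: str = "both"  # negative | positive | both

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("r2_min must be in [0, 1]")
        if self.direction not in ("negative", "positive", "both"):
            raise ValueError("direction must be negative, positive or both")


def delta_fitness(series: GradientSeries, endpoint_a: float, endpoint_b: float) -> pd.Series:
    """Per-gene fitness change ``f(b) - f(a)`` between two gradient endpoints.

    Antisymmetric in the endpoints.  Genes missing fitness at either
    endpoint get NaN (flagged downstream, never silently dropped).
    """
    try:
        ia = series.values.index(endpoint_a)
        ib = series.values.index(endpoint_b)
    except ValueError as exc:
        raise KeyError(f"endpoint not in series {series.values}: {exc}") from None
    return series.fitness.iloc[:, ib] - series.fitness.iloc[:, ia]


def threshold_hits(values: pd.Series, config: ScreenConfig | None = None) -> pd.Index:
    """Genes whose |value| meets the cutoff (boundary inclusive) in the
    configured direction.  NaN values are never hits."""
    config = config or ScreenConfig()
    v = values.astype(float)
    big = v.abs() >= config.cutoff
    if config.direction == "negative":
        big &= v < 0
    elif config.direction == "positive":
        big &= v > 0
    return values.index[big.fillna(False)]


def quadratic_r2(x, y) -> float:
    """Coefficient of determination of an ordinary least-squares quadratic fit.

    Requires at least 4 finite points (3 parameters plus one residual degree
    of freedom); otherwise returns NaN, which downstream treats as a failed
    filter.  The result is clipped to [0, 1].  Degenerate series with zero
    variance in ``y`` get R^2 = 1 when the fit is exact and 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    x, y = x[ok], y[ok]
    if len(y) < 4:
        return float("nan")
    coef = np.polynomial.polynomial.polyfit(x, y, 2)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot < _EPS:
        return 1.0 if ss_res < _EPS else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def screen_gradient(
    series: GradientSeries,
    config: ScreenConfig | None = None,
    endpoints: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Screen a gradient series for genes with large, well-behaved changes.

    A gene is a hit when |delta fitness| between the endpoints meets the
    cutoff and the quadratic fit over the full gradient reaches ``r2_min``.
    Endpoints default to the first and last condition of the series (the two
    extremes); other pairs — e.g. 5 mM vs 1 mM glucose — can be requested.

    Returns a per-gene table with columns ``delta``, ``r2``, ``hit``,
    ``direction`` (negative | positive | none) and ``reason`` for non-hits.
    """
    config = config or ScreenConfig()
    if endpoints is None:
        endpoints = (series.values[0], series.values[-1])
    delta = delta_fitness(series, *endpoints)
    x = np.asarray(series.values, dtype=float)
    r2 = series.fitness.apply(lambda row: quadratic_r2(x, row.to_numpy()), axis=1)

    candidates = threshold_hits(delta, config)
    result = pd.DataFrame({"delta": delta, "r2": r2})
    result["hit"] = False
    result["direction"] = "none"
    result["reason"] = ""
    for g in result.index:
        d, r = result.at[g, "delta"], result.at[g, "r2"]
        if pd.isna(d):
            result.at[g, "reason"] = "missing_endpoint"
        elif g not in candidates:
            result.at[g, "reason"] = "below_cutoff"
        elif pd.isna(r):
            result.at[g, "reason"] = "insufficient_points"
        elif r < config.r2_min:
            result.at[g, "reason"] = "poor_quadratic_fit"
        else:
            result.at[g, "hit"] = True
            result.at[g, "direction"] = "negative" if d < 0 else "positive"
    result.index.name = "gene_id"
    return result


def screen_values(values: pd.Series, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Single-condition screen: magnitude threshold on fitness values only."""
    config = config or ScreenConfig()
    hits = threshold_hits(values, config)
    result = pd.DataFrame({"fitness": values})
    result["hit"] = result.index.isin(hits)
    result["direction"] = np.where(
        result["hit"], np.where(result["fitness"] < 0, "negative", "positive"), "none"
    )
    result.index.name = "gene_id"
    return result
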