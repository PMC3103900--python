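"""Exponential population growth: rate constants, doubling times, slope tests.

Budding *Hydra* populations grow exponentially under regular feeding, so
daily counts follow ln(n / n0) = k t with growth constant k (per day) and
doubling time T2 = ln 2 / k.  Fits go through the origin by default (the
model has no intercept and y(0) = 0 by construction); a free intercept is
available for diagnostic purposes.

Growth constants of two populations are compared by the slope-by-group
interaction F-test of the pooled regression (the standard test of slope
equality between regression lines).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import PopulationCount, ValidationError

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GrowthFit:
    """A fitted exponential growth model for one population."""

    k: float                    # growth constant, per day
    T2: Optional[float]         # doubling time ln2/k (days); None when k <= 0
    intercept: float            # 0.0 when forced through the origin
    r2: float                   # uncentered R^2 for through-origin fits
    residuals: tuple[float, ...]
    n_obs: int
    non_growing: bool = False   # k <= 0: doubling time undefined

    def __post_init__(self) -> None:
        if self.n_obs < 2:
            raise ValidationError("a growth fit needs >= 2 observations")


@dataclass(frozen=True)
class SlopeComparison:
    slope_a: float
    slope_b: float
    slope_diff: float
    F: float
    df_num: int
    df_den: int
    p_value: float


def log_ratio_series(counts: Sequence[PopulationCount]):
    """(t, y) pairs with y = ln(n / n0) for one replicate, sorted by day.

    Requires a day-0 record; its count is the founder number n0, so y(0) = 0
    exactly.
    """
    counts = sorted(counts, key=lambda c: c.day)
    if not counts or counts[0].day != 0:
        raise ValidationError("series must include a day-0 record (the founders)")
    n0 = counts[0].n
    t = np.array([c.day for c in counts], dtype=float)
    y = np.log(np.array([c.n for c in counts], dtype=float) / n0)
    return t, y


def fit_growth(t, y, through_origin: bool = True) -> GrowthFit:
    """Least-squares fit of ln(n/n0) = k t (optionally with free intercept).

    Through the origin k = sum(t*y) / sum(t^2); the reported R^2 is then the
    uncentered one (1 - SSE / sum y^2).  T2 = ln2 / k for growing
    populations; a non-positive k flags the fit as non-growing with T2 None.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("t and y must be matching 1-d arrays")
    distinct = len(np.unique(t))
    if distinct < 2:
        raise ValidationError("need >= 2 distinct days to fit a slope")
    if through_origin:
        denom = float(np.sum(t * t))
        if denom == 0:
            raise ValidationError("all days are 0; slope undefined")
        k = float(np.sum(t * y) / denom)
        intercept = 0.0
        fitted = k * t
        ss_tot = float(np.sum(y ** 2))
    else:
        if distinct < 3:
            raise ValidationError("need >= 3 distinct days for a free-intercept fit")
        k, intercept = np.polyfit(t, y, 1)
        k, intercept = float(k), float(intercept)
        fitted = k * t + intercept
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    resid = y - fitted
    sse = float(np.sum(resid ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    non_growing = k <= 0
    return GrowthFit(
        k=k, T2=None if non_growing else LN2 / k, intercept=intercept, r2=r2,
        residuals=tuple(float(r) for r in resid), n_obs=len(t),
        non_growing=non_growing,
    )


def fit_population(counts: Sequence[PopulationCount], through_origin: bool = True) -> GrowthFit:
    """Convenience: log-ratio transform plus :func:`fit_growth`."""
    t, y = log_ratio_series(counts)
    return fit_growth(t, y, through_origin=through_origin)


def _design(t, g, through_origin):
    # columns: [t, t*g] through origin; [1, g, t, t*g] with intercepts
    if through_origin:
        return np.column_stack([t, t * g])
    return np.column_stack([np.ones_like(t), g, t, t * g])


def compare_growth(series_a, series_b, through_origin: bool = True) -> SlopeComparison:
    """Test equality of growth constants via the interaction F-test.

    Pools both series into one regression with a group indicator and tests
    the slope-by-group interaction term: F = (SSE_common - SSE_separate) /
    (SSE_separate / df).  Noiseless data with genuinely different slopes
    yield the p -> 0 bound; identical series give F = 0, p = 1.
    """
    ta, ya = (np.asarray(v, dtype=float) for v in series_a)
    tb, yb = (np.asarray(v, dtype=float) for v in series_b)
    fit_a = fit_growth(ta, ya, through_origin)
    fit_b = fit_growth(tb, yb, through_origin)
    t = np.concatenate([ta, tb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros_like(ta), np.ones_like(tb)])

    X_full = _design(t, g, through_origin)
    X_red = X_full[:, :-1]  # drop the interaction column
    df_den = len(t) - X_full.shape[1]
    if df_den < 1:
        raise ValidationError("too few observations for a slope comparison")
    # residuals computed explicitly: lstsq's residual output is empty for
    # rank-deficient or exactly-determined systems
    resid_full = y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]
    sse_full = float(resid_full @ resid_full)
    resid_red = y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]
    sse_red = float(resid_red @ resid_red)

    diff = fit_b.k - fit_a.k
    eps = 1e-12 * max(1.0, float(y @ y))
    if sse_full <= eps:
        if abs(diff) <= 1e-12:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F = max(0.0, (sse_red - sse_full)) / (sse_full / df_den)
        p = float(stats.f.sf(F, 1, df_den))
    return SlopeComparison(
        slope_a=fit_a.k, slope_b=fit_b.k, slope_diff=diff,
        F=F, df_num=1, df_den=df_den, p_value=p,
    )


def growth_report(counts: Sequence[PopulationCount], through_origin: bool = True,
                  ratio_days: Sequence[int] = ()):
    """Per-replicate fits plus n/n0 ratios at requested days for one label."""
    by_rep: dict[str, list[PopulationCount]] = {}
    for c in counts:
        by_rep.setdefault(c.replicate_id, []).append(c)
    rows = []
    for rep, clist in sorted(by_rep.items()):
        fit = fit_population(clist, through_origin)
        row = {
            "replicate_id": rep, "k": fit.k, "T2": fit.T2, "r2": fit.r2,
            "n_obs": fit.n_obs, "non_growing": fit.non_growing,
        }
        clist = sorted(clist, key=lambda c: c.day)
        n0 = clist[0].n
        by_day = {c.day: c.n for c in clist}
        for d in ratio_days:
            row[f"ratio_day{d}"] = by_day[d] / n0 if d in by_day else None
        rows.append(row)
    return rows
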