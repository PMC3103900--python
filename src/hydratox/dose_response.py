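"""Trimmed Spearman-Karber estimation of LC50 and LT50.

The Spearman-Karber estimator is a distribution-free estimate of the median
of a tolerance distribution from grouped quantal (dead/alive) data.  On the
log10 dose scale, with adjusted dead fractions :math:`p_i` at positions
:math:`x_i` rising from 0 to 1, the log median is

.. math:: m = \\sum_i (p_{i+1} - p_i)\\,\\frac{x_i + x_{i+1}}{2},

i.e. the mean of the tolerance distribution whose CDF is the linear
interpolant of the response curve.  The pipeline is

1. :func:`smooth_monotone` — weighted pool-adjacent-violators (PAVA) fit,
   giving the monotone non-decreasing curve closest to the observed
   fractions in weighted least squares (weights = group sizes);
2. :func:`trim_curve` — optional Hamilton-style trimming: cut the tails
   below ``alpha`` and above ``1 - alpha`` (crossings located by linear
   interpolation) and rescale the remaining response to [0, 1];
3. :func:`sk_log_median` — the summation above;
4. :func:`sk_confidence` — the classic binomial delta-method variance

.. math:: V(m) = \\sum_{i\\ \\mathrm{interior}}
          \\frac{p_i (1 - p_i)\\,(x_{i+1} - x_{i-1})^2}{4 (n_i - 1)},

   with normal-quantile confidence bounds back-transformed to nM (or hr).

A curve that never reaches 0% or 100% mortality cannot bracket the median;
such series are reported *not estimable* rather than extrapolated, unless
the conventional endpoint-extension rule is explicitly enabled
(``RunConfig.extend``), which appends 0%/100% groups one mean log-step
outside the tested range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .records import AXIS_DOSE, AXIS_TIME, QuantalSeries, RunConfig, ValidationError


class NotEstimableError(ValueError):
    """The response curve cannot bracket the median at the tested levels."""


class VarianceUndefinedError(ValueError):
    """An interior group has fewer than 2 animals; V(m) is undefined."""


@dataclass(frozen=True)
class SmoothedCurve:
    """A monotone-adjusted quantal response curve on the log10 axis."""

    x: tuple[float, ...]       # log10 dose (nM) or log10 time (hr)
    p_raw: tuple[float, ...]   # observed dead fractions
    p_adj: tuple[float, ...]   # monotone non-decreasing adjusted fractions
    n: tuple[int, ...]         # group sizes

    def __post_init__(self) -> None:
        k = len(self.x)
        if not (len(self.p_adj) == len(self.n) == k and len(self.p_raw) == k):
            raise ValidationError("curve arrays must have equal length")
        p = np.asarray(self.p_adj)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValidationError("p_adj must lie in [0, 1]")
        if np.any(np.diff(p) < -1e-12):
            raise ValidationError("p_adj must be non-decreasing")


@dataclass(frozen=True)
class SKEstimate:
    """A Spearman-Karber median with its delta-method confidence interval.

    ``m`` is the log10 median; ``point = 10**m`` is on the original scale
    (nM for dose series, hr for time series).  ``estimable`` is False when
    the curve could not bracket the median, in which case the numeric fields
    are None and ``reason`` explains why (rendered as an em-dash in tables).
    """

    label: str
    axis: str
    trim: float
    confidence: float
    m: Optional[float]
    point: Optional[float]
    variance: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    estimable: bool = True
    reason: Optional[str] = None

    @property
    def se_log10(self) -> Optional[float]:
        if self.variance is None:
            return None
        return float(np.sqrt(self.variance))


def pava(y, w):
    """Weighted pool-adjacent-violators: monotone non-decreasing WLS fit.

    Scans left to right keeping a stack of level blocks; whenever a block
    value drops below its predecessor the two are merged at their weighted
    mean.  The result minimises sum(w * (fit - y)**2) over non-decreasing
    sequences and conserves the weighted mean within every pooled block.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape != w.shape or y.ndim != 1:
        raise ValidationError("pava expects matching 1-d arrays")
    if np.any(w <= 0):
        raise ValidationError("pava weights must be positive")
    vals: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        wts.append(float(wi))
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            counts[-2] += counts[-1]
            vals[-2] = v
            del vals[-1], wts[-1], counts[-1]
        # merging can create a new violation further left; the while loop
        # above keeps merging until the stack is monotone again
    return np.repeat(vals, counts)


def smooth_monotone(series: QuantalSeries) -> SmoothedCurve:
    """PAVA-smooth a quantal series on the log10 axis (weights = group sizes)."""
    x = np.log10(np.asarray(series.axis_values, dtype=float))
    p_raw = np.asarray(series.fractions, dtype=float)
    n = np.asarray(series.n_exposed, dtype=float)
    p_adj = pava(p_raw, n)
    return SmoothedCurve(
        x=tuple(x), p_raw=tuple(p_raw), p_adj=tuple(np.clip(p_adj, 0.0, 1.0)),
        n=tuple(int(v) for v in n),
    )


def extend_curve(curve: SmoothedCurve) -> SmoothedCurve:
    """Conventional endpoint extension: add 0%/100% one mean log-step outside.

    Applied only when the corresponding end of the smoothed curve falls short
    of 0 (or 1).  The appended pseudo-groups reuse the adjacent group size;
    they are terminal, so they never enter the variance sum.
    """
    x = list(curve.x)
    p_raw = list(curve.p_raw)
    p_adj = list(curve.p_adj)
    n = list(curve.n)
    step = float(np.mean(np.diff(curve.x)))
    if p_adj[0] > 0.0:
        x.insert(0, x[0] - step)
        p_raw.insert(0, 0.0)
        p_adj.insert(0, 0.0)
        n.insert(0, n[0])
    if p_adj[-1] < 1.0:
        x.append(x[-1] + step)
        p_raw.append(1.0)
        p_adj.append(1.0)
        n.append(n[-1])
    return SmoothedCurve(x=tuple(x), p_raw=tuple(p_raw), p_adj=tuple(p_adj), n=tuple(n))


def _crossing_low(x, p, level):
    """x where p last rises through `level` from below (end of any flat run)."""
    idx = None
    for i in range(len(p) - 1):
        if p[i] <= level < p[i + 1]:
            idx = i
    if idx is None:
        raise NotEstimableError(
            f"response never rises through {level:.3g} within the tested range"
        )
    i = idx
    frac = (level - p[i]) / (p[i + 1] - p[i])
    return x[i] + frac * (x[i + 1] - x[i]), i


def _crossing_high(x, p, level):
    """x where p first rises through `level` (start of any flat run at it)."""
    for i in range(len(p) - 1):
        if p[i] < level <= p[i + 1]:
            frac = (level - p[i]) / (p[i + 1] - p[i])
            return x[i] + frac * (x[i + 1] - x[i]), i + 1
    raise NotEstimableError(
        f"response never reaches {level:.3g} within the tested range"
    )


def trim_curve(curve: SmoothedCurve, alpha: float) -> SmoothedCurve:
    """Trim the response tails below alpha and above 1 - alpha and rescale.

    The x positions where the adjusted curve crosses ``alpha`` and
    ``1 - alpha`` are found by linear interpolation on the (x, p_adj)
    polyline and become the new endpoints, carrying rescaled responses
    p' = (p - alpha) / (1 - 2 alpha) of exactly 0 and 1.  ``alpha = 0`` is
    the identity trim (the untrimmed estimator), valid only when the curve
    already spans 0..1.
    """
    if not 0 <= alpha < 0.5:
        raise ValidationError(f"trim must be in [0, 0.5), got {alpha}")
    p = np.asarray(curve.p_adj, dtype=float)
    x = np.asarray(curve.x, dtype=float)
    if alpha == 0.0:
        if p[0] > 0.0 or p[-1] < 1.0:
            raise NotEstimableError(
                "adjusted response does not span 0%..100% at the tested levels"
            )
        return curve
    x_lo, i_lo = _crossing_low(x, p, alpha)
    x_hi, i_hi = _crossing_high(x, p, 1.0 - alpha)
    keep = [j for j in range(len(x)) if x_lo < x[j] < x_hi and alpha < p[j] < 1.0 - alpha]
    new_x = [x_lo] + [x[j] for j in keep] + [x_hi]
    scale = 1.0 - 2.0 * alpha
    new_p = [0.0] + [float((p[j] - alpha) / scale) for j in keep] + [1.0]
    n_arr = list(curve.n)
    new_n = [n_arr[min(i_lo, len(n_arr) - 1)]] + [n_arr[j] for j in keep] + [n_arr[i_hi]]
    new_raw = [float("nan")] + [curve.p_raw[j] for j in keep] + [float("nan")]
    return SmoothedCurve(
        x=tuple(new_x), p_raw=tuple(new_raw),
        p_adj=tuple(np.clip(new_p, 0.0, 1.0)), n=tuple(new_n),
    )


def sk_log_median(curve: SmoothedCurve) -> float:
    """Spearman-Karber log10 median of a curve spanning p = 0 .. 1."""
    p = np.asarray(curve.p_adj, dtype=float)
    x = np.asarray(curve.x, dtype=float)
    if p[0] > 1e-12 or p[-1] < 1 - 1e-12:
        raise NotEstimableError(
            "adjusted response must start at 0 and end at 1 (after trim/extension)"
        )
    return float(np.sum(np.diff(p) * (x[:-1] + x[1:]) / 2.0))


def sk_confidence(curve: SmoothedCurve, m: float, level: float = 0.95):
    """Delta-method variance of m and back-transformed confidence bounds.

    Only interior groups contribute (the terminal groups have p(1-p) = 0 in
    estimable cases); each needs n_i >= 2 for the n-1 denominator.
    Returns ``(variance, ci_low, ci_high)`` with the bounds on the original
    (nM / hr) scale.
    """
    p = np.asarray(curve.p_adj, dtype=float)
    x = np.asarray(curve.x, dtype=float)
    n = np.asarray(curve.n, dtype=float)
    v = 0.0
    for i in range(1, len(x) - 1):
        if n[i] < 2:
            raise VarianceUndefinedError(
                f"interior group at x={x[i]:.4g} has n={int(n[i])} < 2"
            )
        v += p[i] * (1 - p[i]) * (x[i + 1] - x[i - 1]) ** 2 / (4.0 * (n[i] - 1.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(v)
    return float(v), float(10 ** (m - half)), float(10 ** (m + half))


def _estimate(series: QuantalSeries, config: RunConfig, axis: str) -> SKEstimate:
    if series.axis != axis:
        raise ValidationError(f"expected a {axis}-axis series, got {series.axis}")
    try:
        curve = smooth_monotone(series)
        if config.extend:
            curve = extend_curve(curve)
        curve = trim_curve(curve, config.trim)
        m = sk_log_median(curve)
        variance, ci_low, ci_high = sk_confidence(curve, m, config.confidence)
    except NotEstimableError as exc:
        return SKEstimate(
            label=series.label, axis=axis, trim=config.trim,
            confidence=config.confidence, m=None, point=None, variance=None,
            ci_low=None, ci_high=None, estimable=False, reason=str(exc),
        )
    return SKEstimate(
        label=series.label, axis=axis, trim=config.trim,
        confidence=config.confidence, m=m, point=float(10 ** m),
        variance=variance, ci_low=ci_low, ci_high=ci_high,
    )


def estimate_lc50(series: QuantalSeries, config: RunConfig = RunConfig()) -> SKEstimate:
    """Median lethal concentration (nM) from a dose-axis quantal series."""
    return _estimate(series, config, AXIS_DOSE)


def estimate_lt50(series: QuantalSeries, config: RunConfig = RunConfig()) -> SKEstimate:
    """Median lethal time (hr) from cumulative mortality at one fixed dose.

    The groups are cumulative dead counts at increasing observation times;
    sampling noise that breaks monotonicity is pooled by the same PAVA step.
    """
    return _estimate(series, config, AXIS_TIME)
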