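"""Ordinal morphology scoring: summaries, death classification, Friedman test.

Animals are scored on the 1-10 Wilby scale (10 = fully extended healthy
polyp, 1 = disintegrated).  Because *Hydra* can recover from sub-lethal
damage, death is defined per observation time as a score strictly below a
threshold (default 4); the quantal mortality tables that feed the
Spearman-Karber estimator are derived from the scores with exactly that rule.

Median scores across concentrations are compared with the Friedman rank
test (blocks x treatments, mid-ranks for ties, tie-corrected statistic).
For small designs (b * k <= 12) an exact permutation p-value is computed by
enumerating all within-block orderings alongside the chi-square
approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import (
    AXIS_DOSE,
    DoseGroup,
    MorphologyRecord,
    QuantalSeries,
    ValidationError,
)


class EmptyCellError(ValidationError):
    """No score records match the requested (dose, time) cell."""


@dataclass(frozen=True)
class ScorePanel:
    """A collection of morphology scores indexed by dose and observation time."""

    records: tuple[MorphologyRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted({r.dose for r in self.records}))

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(sorted({r.time for r in self.records}))

    def scores_at(self, dose: float, time: float) -> list[int]:
        return [r.score for r in self.records if r.dose == dose and r.time == time]


def median_score(panel: ScorePanel, dose: float, time: float):
    """Median score (midpoint convention for even n) and n for one cell."""
    scores = panel.scores_at(dose, time)
    if not scores:
        raise EmptyCellError(f"no scores at dose={dose} nM, time={time} hr")
    return float(np.median(scores)), len(scores)


def is_dead(score: int, threshold: int = 4) -> bool:
    """Dead iff the score is strictly below the threshold ("lower than 4")."""
    if not 1 <= score <= 10:
        raise ValidationError(f"score must be in 1..10, got {score}")
    return score < threshold


def quantal_from_scores(panel: ScorePanel, time: float, threshold: int = 4) -> QuantalSeries:
    """Derive a dose-axis quantal mortality series from scores at one time.

    Each positive dose becomes one group with n_exposed = animals scored and
    n_dead = animals scoring strictly below the threshold.  Dose-0 controls
    cannot enter the log-dose estimator and are excluded.
    """
    doses = [d for d in panel.doses if d > 0]
    groups = []
    for dose in doses:
        scores = panel.scores_at(dose, time)
        if not scores:
            continue
        groups.append(
            DoseGroup(
                dose=dose,
                n_exposed=len(scores),
                n_dead=sum(is_dead(s, threshold) for s in scores),
                time=time,
            )
        )
    if len(groups) < 2:
        raise ValidationError(
            f"need scores at >= 2 positive doses at time {time} hr for a quantal series"
        )
    return QuantalSeries(groups=tuple(groups), axis=AXIS_DOSE, label=panel.label)


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float                 # chi-square approximation
    p_exact: Optional[float]       # exact permutation p, when b*k <= 12
    ranks: tuple                   # b x k within-block mid-ranks
    blocks: tuple                  # block labels (e.g. observation times)
    treatments: tuple              # treatment labels (e.g. doses)


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a b x k mid-rank matrix.

    chi2 = (k-1) * sum_j (R_j - b(k+1)/2)^2 / (sum r_ij^2 - b k (k+1)^2 / 4).
    Without ties this reduces to 12/(b k (k+1)) * sum R_j^2 - 3 b (k+1).
    A fully tied panel (denominator 0) carries no ordering information and
    scores 0.
    """
    b, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum((col_sums - b * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranks ** 2)) - b * k * (k + 1) ** 2 / 4.0
    if den <= 1e-12:
        return 0.0
    return num / den


def friedman_from_matrix(values: np.ndarray):
    """Friedman test on a b x k matrix (rows = blocks, columns = treatments)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expected a blocks x treatments matrix")
    b, k = values.shape
    if k < 2:
        raise ValidationError(f"need >= 2 treatments, got {k}")
    if np.any(np.isnan(values)):
        ij = np.argwhere(np.isnan(values))[0]
        raise ValidationError(f"incomplete design: missing cell (block {ij[0]}, treatment {ij[1]})")
    ranks = np.vstack([stats.rankdata(row) for row in values])
    statistic = _friedman_statistic(ranks)
    df = k - 1
    p_value = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    p_exact = None
    if b * k <= 12:
        p_exact = _exact_permutation_p(ranks, statistic)
    return statistic, df, p_value, p_exact, ranks


def _exact_permutation_p(ranks: np.ndarray, observed: float) -> float:
    """Exact p by enumerating every within-block permutation of the ranks.

    Under the null all k! orderings of each block are equally likely; the
    tie-correction denominator is permutation-invariant, so the statistic
    only changes through the column sums.
    """
    b, k = ranks.shape
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = len(perms) ** b
    block_perms = [[row[list(p)] for p in perms] for row in ranks]
    for combo in itertools.product(*block_perms):
        stat = _friedman_statistic(np.vstack(combo))
        if stat >= observed - 1e-9:
            count += 1
    return count / total


def friedman_test(panel: ScorePanel, blocks: str = "time") -> FriedmanResult:
    """Friedman test on median scores; blocks default to observation times.

    Each (block, treatment) cell is aggregated to its median score; the
    design must be complete.  ``blocks="time"`` treats observation times as
    blocks and doses as treatments; ``blocks="dose"`` transposes that.
    """
    if blocks not in ("time", "dose"):
        raise ValidationError(f"blocks must be 'time' or 'dose', got {blocks!r}")
    times, doses = panel.times, panel.doses
    block_vals, treat_vals = (times, doses) if blocks == "time" else (doses, times)
    if len(treat_vals) < 2:
        raise ValidationError(f"need >= 2 treatments, got {len(treat_vals)}")
    mat = np.empty((len(block_vals), len(treat_vals)))
    for i, bv in enumerate(block_vals):
        for j, tv in enumerate(treat_vals):
            dose, time = (tv, bv) if blocks == "time" else (bv, tv)
            cell = panel.scores_at(dose, time)
            if not cell:
                raise EmptyCellError(
                    f"incomplete design: no scores at dose={dose}, time={time}"
                )
            mat[i, j] = np.median(cell)
    statistic, df, p_value, p_exact, ranks = friedman_from_matrix(mat)
    return FriedmanResult(
        statistic=statistic, df=df, p_value=p_value, p_exact=p_exact,
        ranks=tuple(map(tuple, ranks)), blocks=tuple(block_vals),
        treatments=tuple(treat_vals),
    )


def median_score_table(panel: ScorePanel):
    """All (dose, time) -> (median, n) summaries, sorted by dose then time."""
    rows = []
    for dose in panel.doses:
        for time in panel.times:
            scores = panel.scores_at(dose, time)
            if scores:
                rows.append(
                    {
                        "label": panel.label,
                        "dose_nM": dose,
                        "time_hr": time,
                        "median_score": float(np.median(scores)),
                        "n": len(scores),
                    }
                )
    return rows
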