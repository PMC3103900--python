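"""Record types for *Hydra* bioassay data.

Four kinds of observation circulate through the pipeline:

* grouped quantal mortality counts (:class:`DoseGroup` / :class:`QuantalSeries`),
  the substrate of Spearman-Karber median estimation;
* per-animal ordinal morphology scores on the 1-10 Wilby scale
  (:class:`MorphologyRecord`);
* per-polyp tentacle counts in five relative-length classes during head
  regeneration (:class:`TentacleProfile`);
* daily individual counts of budding populations (:class:`PopulationCount`).

All types validate their invariants on construction and raise
:class:`ValidationError` with a message naming the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

AXIS_DOSE = "dose"
AXIS_TIME = "time"


class ValidationError(ValueError):
    """A record or table violates a documented invariant."""


class SchemaError(ValueError):
    """A table does not match the expected CSV schema."""


@dataclass(frozen=True)
class DoseGroup:
    """One exposure group: ``n_dead`` of ``n_exposed`` animals dead at ``dose`` (nM).

    ``time`` (hr) is the observation time; it doubles as the axis value for
    time-axis (LT50) series, where ``dose`` is the fixed test concentration.
    """

    dose: float
    n_exposed: int
    n_dead: int
    time: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose", float(self.dose))
        if self.time is not None:
            object.__setattr__(self, "time", float(self.time))
        if not self.dose > 0:
            raise ValidationError(f"dose must be > 0, got {self.dose}")
        if self.n_exposed < 1:
            raise ValidationError(f"n_exposed must be >= 1, got {self.n_exposed}")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValidationError(
                f"n_dead must satisfy 0 <= n_dead <= n_exposed, got "
                f"{self.n_dead}/{self.n_exposed}"
            )

    @property
    def fraction_dead(self) -> float:
        return self.n_dead / self.n_exposed


@dataclass(frozen=True)
class QuantalSeries:
    """Ordered dose (or time) groups with exposed/dead counts.

    ``axis`` selects which field of the member groups carries the ordinate:
    ``"dose"`` for concentration-response (LC50) data, ``"time"`` for
    cumulative mortality over observation times at one fixed dose (LT50).
    Axis values must be strictly increasing; duplicates should be pooled
    before construction (see :func:`pool_duplicates`).
    """

    groups: tuple[DoseGroup, ...]
    axis: str = AXIS_DOSE
    label: str = ""

    def __post_init__(self) -> None:
        if self.axis not in (AXIS_DOSE, AXIS_TIME):
            raise ValidationError(f"axis must be 'dose' or 'time', got {self.axis!r}")
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.groups) < 2:
            raise ValidationError("a quantal series needs at least 2 groups")
        vals = self.axis_values
        if any(v is None for v in vals):
            raise ValidationError("time-axis series require a time for every group")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                f"{self.axis} values must be strictly increasing, got {vals}"
            )
        if self.axis == AXIS_TIME:
            doses = {g.dose for g in self.groups}
            if len(doses) > 1:
                raise ValidationError(
                    f"time-axis series must hold one fixed dose, got {sorted(doses)}"
                )

    @property
    def axis_values(self) -> tuple[float, ...]:
        if self.axis == AXIS_DOSE:
            return tuple(g.dose for g in self.groups)
        return tuple(g.time for g in self.groups)

    @property
    def n_exposed(self) -> tuple[int, ...]:
        return tuple(g.n_exposed for g in self.groups)

    @property
    def n_dead(self) -> tuple[int, ...]:
        return tuple(g.n_dead for g in self.groups)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(g.fraction_dead for g in self.groups)


def pool_duplicates(groups: Sequence[DoseGroup], axis: str = AXIS_DOSE) -> list[DoseGroup]:
    """Pool groups sharing an axis value by summing exposed and dead counts.

    Replicate wells at one concentration form a single binomial group for
    Spearman-Karber; pooling preserves total ``n_exposed`` and ``n_dead``.
    Returns groups sorted by axis value.
    """
    pooled: dict[float, list[int]] = {}
    doses: dict[float, DoseGroup] = {}
    for g in groups:
        key = g.dose if axis == AXIS_DOSE else g.time
        if key is None:
            raise ValidationError("cannot pool on a missing time value")
        if key in pooled:
            pooled[key][0] += g.n_exposed
            pooled[key][1] += g.n_dead
        else:
            pooled[key] = [g.n_exposed, g.n_dead]
            doses[key] = g
    out = []
    for key in sorted(pooled):
        n_exp, n_dead = pooled[key]
        proto = doses[key]
        out.append(DoseGroup(dose=proto.dose, n_exposed=n_exp, n_dead=n_dead, time=proto.time))
    return out


@dataclass(frozen=True)
class MorphologyRecord:
    """One Wilby morphology score (1-10) for one animal at one dose and time."""

    animal_id: str
    dose: float
    time: float
    score: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be >= 0, got {self.dose}")
        if not (isinstance(self.score, (int,)) and 1 <= self.score <= 10):
            raise ValidationError(f"score must be an integer in 1..10, got {self.score}")


@dataclass(frozen=True)
class TentacleProfile:
    """Tentacle counts of one polyp on one regeneration day.

    ``counts`` holds five non-negative integers, one per relative-length class
    (nominal lengths 1/8, 1/4, 1/2, 3/4, 1 of a full tentacle).
    """

    polyp_id: str
    day: float
    counts: tuple[int, int, int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.counts) != 5:
            raise ValidationError(f"expected 5 length-class counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValidationError(f"counts must be non-negative, got {self.counts}")
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class PopulationCount:
    """Individual count of one replicate population on one day."""

    replicate_id: str
    day: int
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters shared by all pipeline stages.

    trim
        Spearman-Karber trim fraction alpha in [0, 0.5). 0 disables trimming.
    death_threshold
        Wilby score below which an animal counts as dead (strict ``<``).
    confidence
        Two-sided confidence level for median estimates.
    through_origin
        Fit the growth regression ln(n/n0) = k*t without an intercept.
    extend
        Apply the conventional endpoint-extension rule (0% response one mean
        log-step below the lowest dose, 100% one step above the highest) when
        the smoothed curve does not bracket the medians; off by default, in
        which case such curves are reported not-estimable.
    seed
        Seed for every stochastic component (simulation).
    """

    trim: float = 0.0
    death_threshold: int = 4
    confidence: float = 0.95
    through_origin: bool = True
    extend: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.trim < 0.5:
            raise ValidationError(f"trim must be in [0, 0.5), got {self.trim}")
        if not 1 <= self.death_threshold <= 10:
            raise ValidationError(
                f"death_threshold must be in 1..10, got {self.death_threshold}"
            )
        if not 0 < self.confidence < 1:
            raise ValidationError(f"confidence must be in (0,1), got {self.confidence}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key/value YAML config; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
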