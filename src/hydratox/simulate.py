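"""Synthetic bioassay generator with known ground truth.

Emulates the four kinds of data the analyses consume, with the statistical
structure they assume:

* **Quantal mortality** — each animal carries a log-logistic (or probit)
  tolerance; dead counts are binomial with
  ``p(d) = 1 / (1 + (lc50/d)^hill)``, so the true median is ``lc50`` exactly.
* **Joint dose-time mortality** — each animal draws a log-logistic lifetime
  whose median scales with dose as ``lt50_ref * (d / dose_ref)^(-gamma)``;
  cumulative dead counts over time and dose-response tables at each time are
  marginals of the same animals, so LC50 falls with observation time and
  LT50 falls with dose, by construction.
* **Ordinal morphology scores** — each animal's score starts at 10 and
  decays with the fraction of its latent lifetime already spent, crossing
  the death threshold (score < 4) exactly at its death time, plus ordinal
  observation noise of one scale step that never crosses the alive/dead
  boundary.  Scores and mortality generated from the same model and seed
  are therefore mutually consistent.
* **Tentacle regeneration** — per-tentacle emergence times with exponential
  spacings (mean ``delay_factor / emergence_rate``), logistic elongation of
  relative length afterwards, binned into the five length classes.
* **Budding population growth** — a Yule birth process with per-capita rate
  ``k_true`` from ``n0`` founders (expected count ``n0 * exp(k t)``), or a
  deterministic rounded exponential.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats

from .io import SCHEMAS, quantal_to_frame, write_results
from .morphology import ScorePanel
from .records import (
    AXIS_DOSE,
    AXIS_TIME,
    DoseGroup,
    MorphologyRecord,
    PopulationCount,
    QuantalSeries,
    TentacleProfile,
    ValidationError,
)
from .regeneration import length_class

LOG_LOGISTIC = "log-logistic"
PROBIT = "probit"


@dataclass(frozen=True)
class ToleranceModel:
    """Dose-tolerance distribution with median exactly ``lc50``."""

    lc50: float
    hill: float
    form: str = LOG_LOGISTIC

    def __post_init__(self) -> None:
        if self.lc50 <= 0 or self.hill <= 0:
            raise ValidationError("lc50 and hill must be > 0")
        if self.form not in (LOG_LOGISTIC, PROBIT):
            raise ValidationError(f"unknown tolerance form {self.form!r}")

    def p_dead(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        if self.form == LOG_LOGISTIC:
            return 1.0 / (1.0 + (self.lc50 / d) ** self.hill)
        return stats.norm.cdf(self.hill * (np.log10(d) - np.log10(self.lc50)))


@dataclass(frozen=True)
class HazardModel:
    """Dose-dependent log-logistic lifetimes.

    Median lifetime at dose d is ``lt50_ref * (d / dose_ref)**(-dose_exponent)``
    (hr); ``shape`` is the log-logistic shape of the lifetime distribution
    (larger = tighter around the median).
    """

    lt50_ref: float
    dose_ref: float
    dose_exponent: float
    shape: float = 6.0

    def __post_init__(self) -> None:
        if min(self.lt50_ref, self.dose_ref, self.dose_exponent, self.shape) <= 0:
            raise ValidationError("all hazard parameters must be > 0")

    def median_lifetime(self, dose: float) -> float:
        if dose == 0:
            return float("inf")
        return self.lt50_ref * (dose / self.dose_ref) ** (-self.dose_exponent)

    def draw_lifetimes(self, dose: float, n: int, rng: np.random.Generator) -> np.ndarray:
        m = self.median_lifetime(dose)
        u = rng.uniform(size=n)
        if not np.isfinite(m):
            return np.full(n, np.inf)
        return m * (u / (1.0 - u)) ** (1.0 / self.shape)


@dataclass(frozen=True)
class RegenModel:
    """Tentacle regeneration kinetics; ``delay_factor = 1`` is the control."""

    emergence_rate: float = 2.5   # tentacles/day (control)
    growth_rate: float = 0.8      # logistic elongation rate, 1/day
    delay_factor: float = 1.0     # treatment multiplier on emergence spacing
    n_target: int = 8             # tentacles regrown at completion

    def __post_init__(self) -> None:
        if self.emergence_rate <= 0 or self.growth_rate <= 0:
            raise ValidationError("rates must be > 0")
        if self.delay_factor < 1:
            raise ValidationError("delay_factor must be >= 1")
        if self.n_target < 1:
            raise ValidationError("n_target must be >= 1")


@dataclass(frozen=True)
class BuddingModel:
    """Budding population growth from ``n0`` founders."""

    k_true: float                 # per-capita budding rate, per day
    n0: int = 4
    scheme: str = "birth-process"  # or "deterministic-rounded"

    def __post_init__(self) -> None:
        if self.k_true < 0:
            raise ValidationError("k_true must be >= 0")
        if self.n0 < 1:
            raise ValidationError("n0 must be >= 1")
        if self.scheme not in ("birth-process", "deterministic-rounded"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")


def sim_quantal(doses: Sequence[float], n_per_group: int, model: ToleranceModel,
                seed: int, label: str = "", time: Optional[float] = None) -> QuantalSeries:
    """Binomial dead counts at each dose under the tolerance model."""
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    doses = sorted(float(d) for d in doses)
    if any(d <= 0 for d in doses):
        raise ValidationError("doses must be > 0")
    rng = np.random.default_rng(seed)
    p = model.p_dead(doses)
    dead = rng.binomial(n_per_group, p)
    groups = tuple(
        DoseGroup(dose=d, n_exposed=n_per_group, n_dead=int(k), time=time)
        for d, k in zip(doses, dead)
    )
    return QuantalSeries(groups=groups, axis=AXIS_DOSE, label=label)


def _draw_all_lifetimes(doses, n_per_group, model: HazardModel, rng):
    """Per-dose lifetime arrays; the single source of deaths for a cohort."""
    return {float(d): model.draw_lifetimes(float(d), n_per_group, rng) for d in doses}


@dataclass(frozen=True)
class TimecourseResult:
    """Joint dose-time mortality of one simulated cohort.

    ``by_time`` maps each observation time to a dose-axis quantal series
    (LC50 substrate); ``by_dose`` maps each dose to a time-axis series of
    cumulative dead counts (LT50 substrate).  Both are marginals of the
    same ``lifetimes``.
    """

    by_time: dict
    by_dose: dict
    lifetimes: dict


def sim_timecourse(doses: Sequence[float], times: Sequence[float], n_per_group: int,
                   model: HazardModel, seed: int, label: str = "") -> TimecourseResult:
    doses = sorted(float(d) for d in doses)
    times = sorted(float(t) for t in times)
    if any(d <= 0 for d in doses):
        raise ValidationError("doses must be > 0")
    if any(b <= a for a, b in zip(times, times[1:])) or not times:
        raise ValidationError("times must be strictly increasing and non-empty")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    lifetimes = _draw_all_lifetimes(doses, n_per_group, model, rng)
    # a marginal is only a valid series with >= 2 groups on its axis
    by_time = {}
    if len(doses) >= 2:
        for t in times:
            groups = tuple(
                DoseGroup(dose=d, n_exposed=n_per_group,
                          n_dead=int(np.sum(lifetimes[d] <= t)), time=t)
                for d in doses
            )
            by_time[t] = QuantalSeries(groups=groups, axis=AXIS_DOSE, label=label)
    by_dose = {}
    if len(times) >= 2:
        for d in doses:
            groups = tuple(
                DoseGroup(dose=d, n_exposed=n_per_group,
                          n_dead=int(np.sum(lifetimes[d] <= t)), time=t)
                for t in times
            )
            by_dose[d] = QuantalSeries(groups=groups, axis=AXIS_TIME, label=label)
    return TimecourseResult(by_time=by_time, by_dose=by_dose, lifetimes=lifetimes)


_NOISE_STEPS = np.array([-1, 0, 1])
_NOISE_P = np.array([0.15, 0.70, 0.15])


def _score(time: float, lifetime: float, noise: int) -> int:
    """Ordinal score from the remaining-life fraction.

    Alive animals map the remaining fraction f = 1 - t/L onto 4..10 and dead
    animals onto 1..3; the one-step observation noise is clipped within the
    respective band so the score < 4 death rule reproduces the latent deaths
    exactly.
    """
    if time >= lifetime:
        return int(np.clip(2 + noise, 1, 3))
    f = 1.0 - time / lifetime if np.isfinite(lifetime) else 1.0
    base = 4 + int(round(6 * f))
    return int(np.clip(np.clip(base, 4, 10) + noise, 4, 10))


def sim_scores(doses: Sequence[float], times: Sequence[float], n_per_group: int,
               model: HazardModel, seed: int, label: str = "") -> ScorePanel:
    """Score panel consistent with :func:`sim_timecourse` at the same seed.

    Doses may include 0 (untreated controls keep score 10 up to one noise
    step).  Lifetimes are drawn before any noise, from the same generator
    stream as :func:`sim_timecourse`, so the death sets coincide.
    """
    doses = sorted(float(d) for d in doses)
    times = sorted(float(t) for t in times)
    rng = np.random.default_rng(seed)
    positive = [d for d in doses if d > 0]
    lifetimes = _draw_all_lifetimes(positive, n_per_group, model, rng)
    if 0.0 in doses:
        lifetimes[0.0] = np.full(n_per_group, np.inf)
    records = []
    for d in doses:
        for i in range(n_per_group):
            life = lifetimes[d][i]
            for t in times:
                noise = int(rng.choice(_NOISE_STEPS, p=_NOISE_P))
                records.append(
                    MorphologyRecord(
                        animal_id=f"{label or 'a'}-d{d:g}-{i:02d}",
                        dose=d, time=t, score=_score(t, life, noise), label=label,
                    )
                )
    return ScorePanel(records=tuple(records), label=label)


def sim_regeneration(n_polyps: int, days: Sequence[float], model: RegenModel,
                     seed: int, label: str = "") -> list[TentacleProfile]:
    """Tentacle-count profiles for a group of regenerating polyps.

    Each of the ``n_target`` tentacles emerges after exponential spacings of
    mean ``delay_factor / emergence_rate`` and then elongates logistically:
    relative length ``2 / (1 + exp(-growth_rate * dt)) - 1``, binned by
    :func:`hydratox.regeneration.length_class`.  With ``delay_factor = 1``
    and the same seed the output is identical to the control arm.
    """
    if n_polyps < 1:
        raise ValidationError("n_polyps must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_polyps):
        spacings = model.delay_factor * rng.exponential(
            1.0 / model.emergence_rate, size=model.n_target
        )
        emergence = np.cumsum(spacings)
        for day in days:
            counts = [0, 0, 0, 0, 0]
            for e in emergence:
                if day > e:
                    dt = day - e
                    rel = 2.0 / (1.0 + np.exp(-model.growth_rate * dt)) - 1.0
                    counts[length_class(min(rel, 1.0)) - 1] += 1
            out.append(
                TentacleProfile(
                    polyp_id=f"{label or 'p'}-{j:02d}", day=float(day),
                    counts=tuple(counts), label=label,
                )
            )
    return out


def sim_population(model: BuddingModel, days: int, seed: int,
                   replicate_id: str = "r1", label: str = "") -> list[PopulationCount]:
    """Daily counts of one budding population over ``days`` days.

    Birth-process scheme: each individual buds independently at rate
    ``k_true`` per day (exponential waiting times, total rate n*k), giving a
    Yule process with mean ``n0 * exp(k t)``.  The deterministic scheme
    rounds the exponential curve.  Counts are non-decreasing either way.
    """
    if days < 2:
        raise ValidationError("days must be >= 2")
    rng = np.random.default_rng(seed)
    counts = []
    if model.scheme == "deterministic-rounded":
        for day in range(days + 1):
            n = int(round(model.n0 * np.exp(model.k_true * day)))
            counts.append(PopulationCount(replicate_id=replicate_id, day=day,
                                          n=max(n, 1), label=label))
        return counts
    n = model.n0
    t = 0.0
    day_counts = {}
    next_day = 1
    horizon = float(days)
    while next_day <= days:
        wait = rng.exponential(1.0 / (n * model.k_true)) if model.k_true > 0 else np.inf
        if t + wait > horizon and not np.isfinite(t + wait):
            break
        t_next = t + wait
        while next_day <= days and t_next > next_day:
            day_counts[next_day] = n
            next_day += 1
        if t_next > horizon:
            break
        t = t_next
        n += 1
    for day in range(next_day, days + 1):
        day_counts[day] = n
    counts.append(PopulationCount(replicate_id=replicate_id, day=0, n=model.n0, label=label))
    for day in range(1, days + 1):
        counts.append(PopulationCount(replicate_id=replicate_id, day=day,
                                      n=day_counts[day], label=label))
    return counts


# ---------------------------------------------------------------------------
# Scenario files: full-assay parameter sets for end-to-end simulation


@dataclass(frozen=True)
class Scenario:
    """Parameters of one complete simulated assay (one treatment + control).

    The packaged scenarios ``tga_qd`` and ``gsh_qd`` are calibrated so that
    the hazard model's implied 72-hr LC50 and the printed reference LT50s
    match the treatment they mimic; regeneration and growth parameters are
    realistic defaults (see docs/methods.md).
    """

    label: str
    # mortality (joint dose-time hazard)
    lt50_ref_hr: float
    dose_ref_nM: float
    dose_exponent: float
    lifetime_shape: float
    doses_nM: tuple[float, ...]
    times_hr: tuple[float, ...]
    n_per_group: int
    # regeneration
    emergence_rate: float
    elongation_rate: float
    delay_factor: float
    n_polyps: int
    regen_days: int
    # budding growth
    k_treated: float
    k_control: float
    n0: int
    growth_days: int
    n_replicates: int

    @property
    def hazard(self) -> HazardModel:
        return HazardModel(
            lt50_ref=self.lt50_ref_hr, dose_ref=self.dose_ref_nM,
            dose_exponent=self.dose_exponent, shape=self.lifetime_shape,
        )

    def regen(self, treated: bool) -> RegenModel:
        return RegenModel(
            emergence_rate=self.emergence_rate, growth_rate=self.elongation_rate,
            delay_factor=self.delay_factor if treated else 1.0,
        )

    def budding(self, treated: bool) -> BuddingModel:
        return BuddingModel(k_true=self.k_treated if treated else self.k_control,
                            n0=self.n0)

    @property
    def implied_lc50(self) -> dict[float, float]:
        """True LC50 at each observation time: dose where median lifetime = t."""
        return {
            t: self.dose_ref_nM * (self.lt50_ref_hr / t) ** (1.0 / self.dose_exponent)
            for t in self.times_hr
        }


def load_scenario(name_or_path) -> Scenario:
    """Load a scenario from a flat key/value YAML file or a packaged name."""
    p = Path(str(name_or_path))
    if p.exists():
        text = p.read_text()
    else:
        ref = resources.files("hydratox") / "scenarios" / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(
                f"no scenario file {name_or_path!r}; packaged scenarios: tga_qd, gsh_qd"
            )
        text = ref.read_text()
    data = yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("doses_nM", "times_hr"):
        data[key] = tuple(float(v) for v in data[key])
    return Scenario(**data)


def simulate_scenario(scenario: Scenario, seed: int, outdir) -> dict:
    """Run every generator for one scenario and write the four CSV schemas.

    Sub-seeds are derived deterministically from ``seed``; returns the paths
    written.  The tentacle and population tables contain a ``control`` arm
    alongside the treated one so downstream comparisons are self-contained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    tc = sim_timecourse(scenario.doses_nM, scenario.times_hr, scenario.n_per_group,
                        scenario.hazard, seed=seed, label=scenario.label)
    series = [tc.by_time[t] for t in sorted(tc.by_time)]
    series += [tc.by_dose[d] for d in sorted(tc.by_dose)]
    quantal_path = outdir / "quantal.csv"
    quantal_to_frame(series).to_csv(quantal_path, index=False)

    panel = sim_scores((0.0,) + scenario.doses_nM, scenario.times_hr,
                       scenario.n_per_group, scenario.hazard, seed=seed,
                       label=scenario.label)
    scores_path = outdir / "scores.csv"
    pd.DataFrame(
        [
            {"animal_id": r.animal_id, "label": r.label, "dose_nM": r.dose,
             "time_hr": r.time, "score": r.score}
            for r in panel.records
        ],
        columns=SCHEMAS["scores"],
    ).to_csv(scores_path, index=False)

    days = list(range(scenario.regen_days + 1))
    regen = sim_regeneration(scenario.n_polyps, days, scenario.regen(True),
                             seed=seed + 1, label=scenario.label)
    regen += sim_regeneration(scenario.n_polyps, days, scenario.regen(False),
                              seed=seed + 1, label="control")
    tent_path = outdir / "tentacles.csv"
    pd.DataFrame(
        [
            {"polyp_id": r.polyp_id, "label": r.label, "day": r.day,
             **{f"c{k+1}": r.counts[k] for k in range(5)}}
            for r in regen
        ],
        columns=SCHEMAS["tentacles"],
    ).to_csv(tent_path, index=False)

    pop = []
    for arm, treated in ((scenario.label, True), ("control", False)):
        for rep in range(scenario.n_replicates):
            pop += sim_population(scenario.budding(treated), scenario.growth_days,
                                  seed=seed + 100 + rep + (0 if treated else 50),
                                  replicate_id=f"{arm}-r{rep+1}", label=arm)
    pop_path = outdir / "population.csv"
    pd.DataFrame(
        [
            {"replicate_id": c.replicate_id, "label": c.label, "day": c.day, "n": c.n}
            for c in pop
        ],
        columns=SCHEMAS["population"],
    ).to_csv(pop_path, index=False)

    return {"quantal": quantal_path, "scores": scores_path,
            "tentacles": tent_path, "population": pop_path}
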