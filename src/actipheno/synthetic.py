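"""Synthetic actigraphy cohort generator with planted diurnal structure.

Emulates a wrist-accelerometer study in which every participant contributes
seven complete 24-h days of minute-level activity counts.  Each day follows
one of five diurnal intensity templates -- all-day (AD), morning (M), evening
(E), bi-phasic (BP) and irregular-morning (IM) -- and each participant belongs
to one of four weekly behaviors defined by the mixture of daily patterns they
draw (AD-dominant, M-dominant, AD+M-dominant, E-dominant).  Depressive-symptom
status is planted on the log-odds scale per behavior, and PHQ-9 items are
drawn consistently with that status, so every downstream stage of the pipeline
has known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .phq9 import PHQ9_THRESHOLD

PATTERN_NAMES: tuple[str, ...] = ("AD", "M", "E", "BP", "IM")
BEHAVIOR_NAMES: tuple[str, ...] = ("AD_dom", "M_dom", "ADM_dom", "E_dom")

WORK_CATEGORIES: tuple[str, ...] = (
    "Working",
    "WithJobNotAtWork",
    "LookingForWork",
    "NotWorking",
)

_HOURS = np.arange(24.0)


def _bump(center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((_HOURS - center) / width) ** 2)


def _plateau(rise: float, fall: float, height: float, slope: float = 0.8) -> np.ndarray:
    up = 1.0 / (1.0 + np.exp(-(_HOURS - rise) / slope))
    down = 1.0 / (1.0 + np.exp((_HOURS - fall) / slope))
    return height * up * down


@dataclass(frozen=True)
class PatternTemplate:
    """One diurnal intensity template.

    intensity is in counts/hour; jitter is the SD (hours) of the per-day
    circular peak shift, nonzero only for the irregular-morning pattern.
    """

    name: str
    intensity: np.ndarray
    jitter: float = 0.0

    def standardized(self) -> np.ndarray:
        """Template on the z-score scale used for clustering and naming."""
        v = np.asarray(self.intensity, dtype=float)
        return (v - v.mean()) / v.std()


def generate_pattern_template(name: str, rng: np.random.Generator | None = None) -> PatternTemplate:
    """Build the named diurnal template.

    Shapes are smooth bump/plateau curves satisfying the qualitative
    constraints of each pattern: E peaks between 18:00 and 21:00, M peaks in
    the 07-10 window, BP has two peaks at least 6 h apart, AD is flat
    (max/min < 1.5) across the 08-19 waking window, and IM is a broad,
    two-lobed morning shape whose peak is circularly shifted day to day.
    The rng argument is accepted for interface symmetry; templates are
    deterministic.
    """
    base = 60.0
    if name == "AD":
        intensity = base + _plateau(7.2, 19.8, 620.0)
    elif name == "M":
        intensity = base + _bump(8.3, 1.7, 1500.0)
    elif name == "E":
        intensity = base + _bump(19.0, 1.7, 1400.0)
    elif name == "BP":
        intensity = base + _bump(8.0, 1.5, 950.0) + _bump(19.0, 1.5, 950.0)
    elif name == "IM":
        intensity = 90.0 + _bump(6.0, 1.3, 520.0) + _bump(12.0, 2.6, 480.0)
        return PatternTemplate(name, intensity, jitter=1.5)
    else:
        raise MalformedInputError(f"unknown pattern name: {name!r}")
    return PatternTemplate(name, intensity)


def default_templates(rng: np.random.Generator | None = None) -> dict[str, PatternTemplate]:
    return {name: generate_pattern_template(name, rng) for name in PATTERN_NAMES}


def _mixture(dominant: dict[str, float]) -> np.ndarray:
    """Spread non-dominant mass uniformly over the remaining patterns."""
    probs = np.zeros(len(PATTERN_NAMES))
    for name, p in dominant.items():
        probs[PATTERN_NAMES.index(name)] = p
    rest = np.flatnonzero(probs == 0)
    probs[rest] = (1.0 - probs.sum()) / len(rest)
    return probs


@dataclass(frozen=True)
class BehaviorSpec:
    """A weekly behavior: a per-day pattern mixture plus a depression log-odds offset."""

    name: str
    pattern_probs: np.ndarray
    depression_logit_offset: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pattern_probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise MalformedInputError("pattern_probs must be a 5-vector of probabilities summing to 1")
        object.__setattr__(self, "pattern_probs", p)


# Dominant-component means mirror the observed per-behavior relative
# frequencies (AD-dom 0.79, M-dom 0.83, AD+M 0.43/0.44, E-dom 0.49).
_DOMINANT_MASS: dict[str, dict[str, float]] = {
    "AD_dom": {"AD": 0.79},
    "M_dom": {"M": 0.83},
    "ADM_dom": {"AD": 0.43, "M": 0.44},
    "E_dom": {"E": 0.49},
}


def default_behavior_specs(effect_ors: dict[str, float] | None = None) -> dict[str, BehaviorSpec]:
    """The four behaviors with their pattern mixtures and planted effects."""
    ors = dict(DEFAULT_EFFECT_ORS)
    if effect_ors:
        ors.update(effect_ors)
    return {
        name: BehaviorSpec(name, _mixture(_DOMINANT_MASS[name]), float(np.log(ors[name])))
        for name in BEHAVIOR_NAMES
    }


@dataclass(frozen=True)
class CovariateParams:
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_prop: float
    work_probs: tuple[float, float, float, float]


# Per-behavior covariate marginals (age, BMI, sex, work situation) chosen to
# match the observed cohort composition of each behavior group.
DEFAULT_COVARIATES: dict[str, CovariateParams] = {
    "AD_dom": CovariateParams(44.68, 18.52, 28.49, 7.09, 0.4447, (0.4634, 0.0247, 0.0702, 0.4417)),
    "M_dom": CovariateParams(55.82, 16.43, 29.01, 6.15, 0.5222, (0.5264, 0.0145, 0.0263, 0.4328)),
    "ADM_dom": CovariateParams(47.47, 17.60, 29.18, 7.03, 0.4912, (0.5395, 0.0112, 0.0381, 0.4112)),
    "E_dom": CovariateParams(34.75, 15.76, 28.83, 7.96, 0.5527, (0.4740, 0.0169, 0.0942, 0.4149)),
}

# Crude odds ratios vs the morning-dominant reference.
DEFAULT_EFFECT_ORS: dict[str, float] = {
    "AD_dom": 1.21,
    "M_dom": 1.0,
    "ADM_dom": 1.24,
    "E_dom": 2.48,
}

# Behavior prevalences in the analysis cohort (AD, M, AD+M, E dominant).
DEFAULT_BEHAVIOR_MIX: tuple[float, float, float, float] = (0.2386, 0.3404, 0.2534, 0.1676)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    noise is the negative-binomial dispersion (shape) parameter for
    minute-level counts; larger means closer to Poisson, and None selects the
    Poisson limit exactly.
    """

    n_participants: int = 200
    behavior_mix: tuple[float, float, float, float] = DEFAULT_BEHAVIOR_MIX
    noise: float | None = 10.0
    baseline_prevalence: float = 0.0699
    effect_ors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_ORS))
    covariate_params: dict[str, CovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    seed: int = 0

    def validate(self) -> None:
        mix = np.asarray(self.behavior_mix, dtype=float)
        if mix.shape != (4,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-8:
            raise MalformedInputError("behavior_mix must be 4 nonnegative values summing to 1")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise MalformedInputError("baseline_prevalence must lie in (0, 1)")
        if any(v <= 0 for v in self.effect_ors.values()):
            raise MalformedInputError("effect_ors must be positive")
        if self.n_participants < 0:
            raise MalformedInputError("n_participants must be nonnegative")
        if self.noise is not None and not self.noise > 0:
            raise MalformedInputError("noise dispersion must be positive (or None for Poisson)")


def _draw_counts(mu: np.ndarray, dispersion: float | None, rng: np.random.Generator) -> np.ndarray:
    """Minute counts with mean mu: NB(dispersion) or Poisson in the limit."""
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_participant_week(
    spec: BehaviorSpec,
    templates: dict[str, PatternTemplate],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Seven days of 1440 minute counts plus the true per-day pattern labels.

    Each day's pattern is drawn from the behavior's mixture; minute counts are
    negative-binomial with mean template-intensity/60 for the minute's hour,
    with the IM template's hour index circularly shifted by a per-day
    Normal(0, jitter) draw rounded to whole hours.
    """
    missing = [n for n in PATTERN_NAMES if n not in templates]
    if missing:
        raise MalformedInputError(f"templates missing patterns: {missing}")
    week = np.empty((7, 1440), dtype=np.int64)
    labels: list[str] = []
    for d in range(7):
        name = PATTERN_NAMES[rng.choice(5, p=spec.pattern_probs)]
        tpl = templates[name]
        hourly = np.asarray(tpl.intensity, dtype=float)
        if tpl.jitter > 0:
            shift = int(np.rint(rng.normal(0.0, tpl.jitter)))
            hourly = np.roll(hourly, shift)
        mu = np.repeat(hourly / 60.0, 60)
        week[d] = _draw_counts(mu, cfg.noise, rng)
        labels.append(name)
    return week, labels


_PHQ9_ITEM_PROBS = {
    # item-level response distributions over scores {0,1,2,3}; items are
    # resampled until the total is consistent with the planted status
    True: (0.1, 0.3, 0.3, 0.3),
    False: (0.6, 0.3, 0.1, 0.0),
}


def _draw_phq9(depressed: bool, rng: np.random.Generator) -> np.ndarray:
    probs = _PHQ9_ITEM_PROBS[depressed]
    while True:
        items = rng.choice(4, size=9, p=probs)
        if (items.sum() >= PHQ9_THRESHOLD) == depressed:
            return items


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def simulate_cohort(
    cfg: SimConfig,
    include_activity: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate (activity table, cohort table, truth tables) for a cohort.

    Returns the long-format activity table (empty when include_activity is
    False -- useful for statistics-only simulations where the minute-level
    signal is not needed), the covariate + PHQ-9 table, and truth tables
    holding the planted per-day patterns and per-participant behaviors and
    depression statuses.  Reproducible: a single seed sequence spawns one
    substream per participant.
    """
    cfg.validate()
    templates = default_templates()
    specs = default_behavior_specs(cfg.effect_ors)
    base_logit = _logit(cfg.baseline_prevalence)

    root = np.random.SeedSequence(cfg.seed)
    cohort_ss, *participant_ss = root.spawn(cfg.n_participants + 1)
    cohort_rng = np.random.default_rng(cohort_ss)
    behaviors = cohort_rng.choice(4, size=cfg.n_participants, p=np.asarray(cfg.behavior_mix))

    activity_rows: list[pd.DataFrame] = []
    cohort_rows: list[dict] = []
    truth_day_rows: list[dict] = []
    truth_part_rows: list[dict] = []
    width = max(4, len(str(max(cfg.n_participants, 1))))

    for i in range(cfg.n_participants):
        pid = f"P{i + 1:0{width}d}"
        rng = np.random.default_rng(participant_ss[i])
        spec = specs[BEHAVIOR_NAMES[behaviors[i]]]
        cov = cfg.covariate_params[spec.name]

        age = float(np.clip(rng.normal(cov.age_mean, cov.age_sd), 18.0, 85.0))
        bmi = float(np.clip(rng.normal(cov.bmi_mean, cov.bmi_sd), 14.0, 60.0))
        gender = "Male" if rng.random() < cov.male_prop else "Female"
        work = WORK_CATEGORIES[rng.choice(4, p=np.asarray(cov.work_probs) / sum(cov.work_probs))]

        p_dep = 1.0 / (1.0 + np.exp(-(base_logit + spec.depression_logit_offset)))
        depressed = bool(rng.random() < p_dep)
        items = _draw_phq9(depressed, rng)

        if include_activity:
            week, labels = simulate_participant_week(spec, templates, cfg, rng)
            activity_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "day_index": np.repeat(np.arange(1, 8), 1440),
                        "minute_of_day": np.tile(np.arange(1440), 7),
                        "count": week.ravel(),
                    }
                )
            )
        else:
            # pattern labels are still drawn so truth tables are complete
            labels = [
                PATTERN_NAMES[rng.choice(5, p=spec.pattern_probs)] for _ in range(7)
            ]

        row: dict = {"participant_id": pid, "age": age, "bmi": bmi, "gender": gender, "work": work}
        row.update({f"phq9_{k + 1}": int(items[k]) for k in range(9)})
        cohort_rows.append(row)
        truth_part_rows.append(
            {"participant_id": pid, "true_behavior": spec.name, "true_depression": depressed}
        )
        truth_day_rows.extend(
            {"participant_id": pid, "day_index": d + 1, "true_pattern": lab}
            for d, lab in enumerate(labels)
        )

    activity_cols = ["participant_id", "day_index", "minute_of_day", "count"]
    cohort_cols = ["participant_id", "age", "bmi", "gender", "work"] + [
        f"phq9_{k}" for k in range(1, 10)
    ]
    activity = (
        pd.concat(activity_rows, ignore_index=True)
        if activity_rows
        else pd.DataFrame(columns=activity_cols)
    )
    cohort = pd.DataFrame(cohort_rows, columns=cohort_cols)
    truth = {
        "days": pd.DataFrame(truth_day_rows, columns=["participant_id", "day_index", "true_pattern"]),
        "participants": pd.DataFrame(
            truth_part_rows, columns=["participant_id", "true_behavior", "true_depression"]
        ),
    }
    return activity, cohort, truth


def nhanes_like_config(n_participants: int = 4242, seed: int = 0, **overrides) -> SimConfig:
    """Convenience config at the analysis-cohort scale with the default planted effects."""
    return replace(SimConfig(), n_participants=n_participants, seed=seed, **overrides)
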