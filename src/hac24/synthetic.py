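"""Synthetic cohorts with the structure the three analyses assume.

The generator emulates an older-adult activity-monitoring study: each person
belongs to one of a small number of latent activity profiles; each wear day
yields hours of sitting, standing, stepping (waking) and time in bed
("sleep"), rescaled so the four behaviors exactly fill the day, whose length
varies slightly around 24 h by the out-of-bed-to-out-of-bed day definition;
person-level covariates are drawn from configurable marginals; and a
continuous cognitive outcome follows a linear model in class membership and
covariates with Gaussian noise.  Ground truth (class labels, coefficients)
is returned for recovery testing.

Activity generation is hierarchical: a profile's sd_hours describes the
*between-person* spread within the class (that is the spread a latent
profile model fit to person-level means sees), so each person first draws a
habitual behavior vector from N(class mean, class SD), and each wear day
then varies around that habit with day-to-day noise
(``within_person_sd_scale`` times the class SD).  Drawing days directly
from the class distribution would shrink the person-level class spread by
sqrt(n_days) after averaging and make the classes far better separated
than the printed profile summaries imply.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import PARTS

BEHAVIORS = PARTS  # (sit, stand, step, sleep), hours/day on the generation scale
WAKING = ("sit", "stand", "step")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSpec:
    """One latent activity profile: mixture weight plus per-behavior
    mean (h/day) and SD (h/day) on the generation scale."""

    label: str
    weight: float
    mean_hours: dict[str, float]
    sd_hours: dict[str, float]
    corr: np.ndarray | None = None  # optional within-class correlation (4x4)

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("profile weight must be in (0, 1]")
        for b in BEHAVIORS:
            if self.mean_hours.get(b, 0.0) <= 0:
                raise ValueError(f"mean_hours[{b!r}] must be > 0")
            if self.sd_hours.get(b, -1.0) < 0:
                raise ValueError(f"sd_hours[{b!r}] must be >= 0")


def default_act_profiles() -> list[ProfileSpec]:
    """The four activity profiles of the motivating older-adult cohort.

    Weights 15.9 / 24.4 / 40.3 / 19.4 % with per-behavior mean (SD) hours per
    day: a most-active group, a moderately-active low-sleeper group, an
    average group, and a least-active group.
    """
    rows = [
        ("most_active", 0.159,
         dict(sit=7.6, stand=5.8, step=1.9, sleep=8.7),
         dict(sit=1.4, stand=1.8, step=0.8, sleep=1.1)),
        ("moderately_active_low_sleep", 0.244,
         dict(sit=9.6, stand=4.7, step=1.7, sleep=7.9),
         dict(sit=1.1, stand=1.1, step=0.5, sleep=1.0)),
        ("average", 0.403,
         dict(sit=10.3, stand=3.5, step=1.3, sleep=8.9),
         dict(sit=1.3, stand=0.9, step=0.4, sleep=0.6)),
        ("least_active", 0.194,
         dict(sit=12.1, stand=2.4, step=0.7, sleep=8.8),
         dict(sit=1.7, stand=1.0, step=0.3, sleep=1.4)),
    ]
    return [ProfileSpec(label, w, m, s) for label, w, m, s in rows]


@dataclass(frozen=True)
class OutcomeModel:
    """Linear outcome model: intercept + class effect + covariate effects + noise.

    `class_effects` holds one value per profile (in profile order); covariate
    effects are keyed by covariate column name.  Defaults reflect a cognitive
    score in SD units with a markedly lower mean in the least-active group.
    """

    intercept: float = 0.61
    class_effects: tuple[float, ...] = (-0.048, 0.018, 0.0, -0.239)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 0.69

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be > 0")


@dataclass(frozen=True)
class CovariateMarginals:
    """Person-level covariate marginals (defaults from the motivating cohort)."""

    age_group_probs: tuple[float, ...] = (0.419, 0.411, 0.170)
    age_group_labels: tuple[str, ...] = ("65-74", "75-84", "85+")
    p_female: float = 0.558
    bmi_mean: float = 27.1
    bmi_sd: float = 4.9
    education_mean: float = 16.8
    education_sd: float = 2.8
    cesd_mean: float = 3.6
    cesd_sd: float = 3.9
    p_good_health: float = 0.921
    p_white: float = 0.902

    def __post_init__(self) -> None:
        probs = list(self.age_group_probs) + [self.p_female, self.p_good_health,
                                              self.p_white]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("covariate probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    n_persons: int = 1000
    n_days: int = 7
    profiles: tuple[ProfileSpec, ...] = tuple(default_act_profiles())
    day_length_mean: float = 1440.0
    day_length_sd: float = 6.0
    within_person_sd_scale: float = 1.0   # day-to-day SD as multiple of class SD
    covariates: CovariateMarginals = CovariateMarginals()
    outcome: OutcomeModel = OutcomeModel()
    missing_covariate_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_days < 1:
            raise ValueError("n_persons and n_days must be >= 1")
        w = sum(p.weight for p in self.profiles)
        if abs(w - 1.0) > 1e-8:
            raise ValueError(f"profile weights sum to {w:.6f}, not 1")
        if not 0.0 <= self.missing_covariate_rate <= 1.0:
            raise ValueError("missing_covariate_rate must be in [0, 1]")


#: covariate columns eligible for missingness (mirrors which fields carry
#: missing values in real cohort tables)
MISSABLE = ("bmi", "cesd", "white")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_positive_normal(rng: np.random.Generator, mean: np.ndarray,
                          sd: np.ndarray, size: int) -> np.ndarray:
    """Truncated-positive normal draws by redrawing non-positive values."""
    out = rng.normal(mean, sd, size=(size, mean.size))
    bad = out <= 0
    tries = 0
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad],
                              np.broadcast_to(sd, out.shape)[bad])
        bad = out <= 0
        tries += 1
        if tries > 1000:  # pathological config (mean far below 0)
            raise ValueError("cannot draw positive behavior hours; "
                             "check profile means/SDs")
    return out


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, dict]:
    """Generate daily records, a person table, and the ground truth.

    Returns
    -------
    daily : DataFrame with person_id, day, sit/stand/step/sleep minutes,
        wear_minutes (waking wear), day_length_minutes.
    persons : DataFrame with person_id, covariates, outcome.
    classes : integer array of true class indices per person.
    truth : dict of the outcome-model coefficients actually used.
    """
    master = np.random.SeedSequence(config.seed)
    ss_class, ss_cov, ss_out, ss_days = master.spawn(4)

    rng = np.random.default_rng(ss_class)
    weights = np.array([p.weight for p in config.profiles])
    classes = rng.choice(len(config.profiles), size=config.n_persons, p=weights)

    # per-person substreams for the daily activity draws
    child_seeds = ss_days.spawn(config.n_persons)
    rows = []
    for i in range(config.n_persons):
        prof = config.profiles[classes[i]]
        prng = np.random.default_rng(child_seeds[i])
        mean = np.array([prof.mean_hours[b] for b in BEHAVIORS])
        sd = np.array([prof.sd_hours[b] for b in BEHAVIORS])
        if np.all(sd == 0):
            hours = np.tile(mean, (config.n_days, 1)).astype(float)
        else:
            habit = _draw_positive_normal(prng, mean, np.maximum(sd, 1e-12),
                                          1)[0]
            day_sd = config.within_person_sd_scale * sd
            if np.all(day_sd == 0):
                hours = np.tile(habit, (config.n_days, 1))
            else:
                hours = _draw_positive_normal(prng, habit,
                                              np.maximum(day_sd, 1e-12),
                                              config.n_days)
        day_len = np.rint(prng.normal(config.day_length_mean,
                                      config.day_length_sd,
                                      size=config.n_days))
        minutes = hours / hours.sum(axis=1, keepdims=True) * day_len[:, None]
        for d in range(config.n_days):
            sit, stand, step, sleep = minutes[d]
            rows.append((i, d, sit, stand, step, sleep,
                         sit + stand + step, day_len[d]))
    daily = pd.DataFrame(rows, columns=[
        "person_id", "day", "sit", "stand", "step", "sleep",
        "wear_minutes", "day_length_minutes"])

    persons = _draw_covariates(config, np.random.default_rng(ss_cov))
    persons["true_class"] = classes
    persons["outcome"] = _draw_outcome(config, persons, classes,
                                       np.random.default_rng(ss_out))

    truth = {
        "intercept": config.outcome.intercept,
        "class_effects": list(config.outcome.class_effects),
        "covariate_effects": dict(config.outcome.covariate_effects),
        "residual_sd": config.outcome.residual_sd,
        "profile_weights": weights.tolist(),
        "seed": config.seed,
    }
    return daily, persons, classes, truth


def _draw_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_persons
    m = config.covariates
    age = rng.choice(m.age_group_labels, size=n,
                     p=np.array(m.age_group_probs) / sum(m.age_group_probs))
    female = rng.random(n) < m.p_female
    bmi = rng.normal(m.bmi_mean, m.bmi_sd, size=n)
    education = rng.normal(m.education_mean, m.education_sd, size=n)
    cesd = np.maximum(rng.normal(m.cesd_mean, m.cesd_sd, size=n), 0.0)
    good_health = rng.random(n) < m.p_good_health
    white = rng.random(n) < m.p_white
    df = pd.DataFrame({
        "person_id": np.arange(n),
        "age_group": age,
        "female": female.astype(float),
        "bmi": bmi,
        "education": education,
        "cesd": cesd,
        "good_health": good_health.astype(float),
        "white": white.astype(float),
    })
    if config.missing_covariate_rate > 0:
        for col in MISSABLE:
            miss = rng.random(n) < config.missing_covariate_rate
            df.loc[miss, col] = np.nan
    return df


def _draw_outcome(config: CohortConfig, persons: pd.DataFrame,
                  classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    om = config.outcome
    eff = np.asarray(om.class_effects, dtype=float)
    if eff.size != len(config.profiles):
        raise ValueError("class_effects length must match number of profiles")
    y = om.intercept + eff[classes]
    for col, beta in om.covariate_effects.items():
        vals = persons[col].to_numpy(dtype=float)
        y = y + beta * np.nan_to_num(vals, nan=np.nanmean(vals))
    return y + rng.normal(0.0, om.residual_sd, size=len(persons))


def generate_null_outcome(config: CohortConfig) -> np.ndarray:
    """Outcome with all class and covariate effects zeroed: intercept + noise
    (+ any covariate effects explicitly left in a custom config are removed)."""
    null_cfg = dataclasses.replace(
        config,
        outcome=dataclasses.replace(
            config.outcome,
            class_effects=tuple(0.0 for _ in config.profiles),
            covariate_effects={}),
    )
    _, persons, _, _ = generate_cohort(null_cfg)
    return persons["outcome"].to_numpy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, daily: pd.DataFrame, persons: pd.DataFrame,
                 config: CohortConfig) -> None:
    """Write daily/person CSVs plus a YAML config snapshot recording the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    daily.to_csv(outdir / "daily.csv", index=False)
    persons.to_csv(outdir / "persons.csv", index=False)
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["profiles"] = [
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in dataclasses.asdict(p).items()}
        for p in config.profiles
    ]
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    profiles = tuple(
        ProfileSpec(label=p["label"], weight=p["weight"],
                    mean_hours=dict(p["mean_hours"]),
                    sd_hours=dict(p["sd_hours"]),
                    corr=None if p.get("corr") is None else np.asarray(p["corr"]))
        for p in d.pop("profiles", [dataclasses.asdict(q) for q in default_act_profiles()])
    )
    cov = CovariateMarginals(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d.pop("covariates", {}).items()})
    out = d.pop("outcome", {})
    if isinstance(out, dict):
        if "class_effects" in out:
            out["class_effects"] = tuple(out["class_effects"])
        out = OutcomeModel(**out)
    return CohortConfig(profiles=profiles, covariates=cov, outcome=out, **d)
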