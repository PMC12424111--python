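"""Synthetic respondents and cohorts for the KS validation pipeline.

A respondent is a small latent-trait model of speeded keypress
performance.  Per-item response latency in condition *c* is lognormal
with median

    m(r, c) = (1000 / base_rate) * condition_cost[c]
              * exp(age_slope * (age - 54.09))
              * exp(-latent_speed * trait_sd)
              * inhibition_cost   (inhibition & switching conditions)
              * switching_cost    (switching condition only)
              * exp(cond_noise_sd * w_{r,c})

and item-level dispersion ``item_sd`` on the log scale.  The shared
terms (age and the general latent speed) make all six subtest scores
strongly positively correlated and negatively correlated with age; the
person-by-condition terms (the cost multipliers and the idiosyncratic
w) keep those correlations below 1 at realistic magnitudes.  Responses
are correct with probability 1 - p_err, where p_err scales a
per-condition base error rate by the respondent's error proneness;
errors press a uniformly random wrong key.

Scores arise mechanistically: each respondent is administered a full
session through the real engine (practice gate plus six timed trials).
An analytic mode computes the expected item count per trial instead of
simulating events, for when only score-level structure is needed at
large n.

Surrogate external-measure scores (WAIS-IV style subtests, trail
making, pegboard, mood inventories) are linear-in-composite stand-ins:
loading times the standardized latent speed-and-age composite plus
independent noise.  They reproduce sign and rough magnitude patterns,
not the real instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .session_engine import (
    Responder,
    SessionResult,
    VirtualClock,
    run_session,
)
from .task_model import (
    CONDITION_ORDER,
    CONDITIONS,
    DIRECTIONS,
    ConditionSpec,
    Direction,
    Phase,
    ResponseRule,
    Stimulus,
    required_response,
)

AGE_MEAN = 54.09
AGE_SD = 16.24
AGE_MIN, AGE_MAX = 18.0, 85.0


@dataclass(frozen=True)
class Respondent:
    """One simulated person: demographics plus latent performance traits."""

    id: str
    age: float
    education: int
    gender: str
    ethnicity: str
    latent_speed: float          # z-score; shared across all six conditions
    inhibition_cost: float       # latency multiplier >= 1 on inhibition conditions
    switching_cost: float        # latency multiplier >= 1 on the switching condition
    error_proneness: float       # multiplies per-condition base error rates

    def __post_init__(self) -> None:
        if not AGE_MIN <= self.age <= AGE_MAX:
            raise ValueError(f"age {self.age} outside [{AGE_MIN}, {AGE_MAX}]")
        if self.education < 12:
            raise ValueError("education must be at least 12 years")
        if self.inhibition_cost < 1 or self.switching_cost < 1:
            raise ValueError("cost multipliers must be >= 1")


@dataclass(frozen=True)
class MeasureSpec:
    """One surrogate external measure: loading on the speed composite,
    reporting scale, and the complete-pair count its missingness targets."""

    name: str
    loading: float
    mean: float
    sd: float
    pairs_n: int


#: Surrogate external measures.  Loadings follow the observed sign pattern:
#: positive for the WAIS-IV-style and interference subtests, negative for
#: the timed trail/pegboard measures (lower raw time = better), and zero
#: for the mood/anxiety inventories (discriminant measures).  pairs_n sets
#: the per-measure missing-completely-at-random rate out of 87.
MEASURE_SPECS: tuple[MeasureSpec, ...] = (
    MeasureSpec("DS", 0.32, 10.5, 3.0, 86),
    MeasureSpec("SS", 0.57, 10.0, 3.0, 84),
    MeasureSpec("CD", 0.67, 9.5, 3.0, 84),
    MeasureSpec("MR", 0.49, 10.0, 3.0, 72),
    MeasureSpec("RDS", 0.21, 10.0, 2.5, 85),
    MeasureSpec("TMT_A", -0.26, 35.0, 15.0, 86),
    MeasureSpec("TMT_B", -0.55, 90.0, 45.0, 84),
    MeasureSpec("OI", 0.53, 100.0, 15.0, 44),
    MeasureSpec("CI", 0.67, 100.0, 15.0, 44),
    MeasureSpec("GPT", -0.61, 75.0, 20.0, 74),
    MeasureSpec("BDI", 0.0, 12.0, 9.0, 60),
    MeasureSpec("BAI", 0.0, 10.0, 8.0, 59),
)

MEASURE_NAMES: tuple[str, ...] = tuple(m.name for m in MEASURE_SPECS)

_DEFAULT_CONDITION_COST = {
    "K1": 1.00, "K2": 1.08, "K3": 1.15, "K4": 1.25, "K5": 1.30, "K6": 1.45,
}
_DEFAULT_BASE_ERROR = {
    "K1": 0.02, "K2": 0.02, "K3": 0.04, "K4": 0.04, "K5": 0.05, "K6": 0.07,
}
_DEFAULT_EDUCATION = {
    12: 0.25, 13: 0.05, 14: 0.15, 15: 0.05, 16: 0.30,
    17: 0.02, 18: 0.12, 19: 0.01, 20: 0.05,
}
_DEFAULT_GENDER = {"female": 49 / 87, "male": 38 / 87}
_DEFAULT_ETHNICITY = {
    "caucasian": 60 / 87,
    "latino": 12 / 87,
    "asian_american": 8 / 87,
    "african_american": 3 / 87,
    "pacific_islander": 2 / 87,
    "middle_eastern": 2 / 87,
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation configuration and default calibration.

    The default numeric values are the package's calibration of the
    latent-trait model: age slope, trait and condition-noise dispersions
    chosen so a large cohort shows all pairwise subtest correlations
    near .8 and age-score correlations near -.55 (see docs/methods.md
    for the variance-decomposition derivation).
    """

    n: int = 87
    seed: int = 0
    mode: str = "engine"                      # "engine" or "analytic"
    base_rate: float = 1.7                    # K1 items per second (median)
    condition_cost: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_COST))
    age_slope: float = 0.0085                 # log-latency per year of age
    trait_sd: float = 0.18                    # person log-speed dispersion
    item_sd: float = 0.35                     # within-trial lognormal sigma
    cond_noise_sd: float = 0.106              # person-by-condition idiosyncrasy
    inhibition_cost_sd: float = 0.11          # folded-normal scale of the multiplier
    switching_cost_sd: float = 0.08
    base_error: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_ERROR))
    error_proneness_sd: float = 0.5           # lognormal sigma of the multiplier
    max_error_rate: float = 0.3
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    education_weights: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_EDUCATION))
    gender_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENDER))
    ethnicity_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ETHNICITY))
    measures: tuple[MeasureSpec, ...] = MEASURE_SPECS
    missingness: bool = False                 # MCAR per-measure gaps when True
    reference_n: int = 87                     # cohort size the pairs_n counts refer to

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.base_rate <= 0 or self.item_sd < 0 or self.trait_sd < 0:
            raise ValueError("rates and dispersions must be positive")
        if self.mode not in ("engine", "analytic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        cc = self.condition_cost
        if not (cc["K1"] <= cc["K3"] <= cc["K5"] <= cc["K6"]
                and cc["K2"] <= cc["K4"] <= cc["K5"]):
            raise ValueError(
                "condition costs must be ordered speeded <= inhibition <= switching"
            )


def sample_respondent(config: SimConfig, rng: np.random.Generator,
                      rid: str = "r0") -> Respondent:
    """Draw one respondent: truncated-normal age on [18, 85], categorical
    demographics from the configured mixtures, standard-normal latent speed,
    folded-normal (>= 1) inhibition/switching cost multipliers, and a
    lognormal error-proneness multiplier."""
    a, b = (AGE_MIN - config.age_mean) / config.age_sd, (AGE_MAX - config.age_mean) / config.age_sd
    age = float(stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                                    random_state=rng))
    edu_levels = list(config.education_weights)
    edu_p = np.array(list(config.education_weights.values()), dtype=float)
    education = int(rng.choice(edu_levels, p=edu_p / edu_p.sum()))
    genders = list(config.gender_weights)
    g_p = np.array(list(config.gender_weights.values()), dtype=float)
    gender = str(rng.choice(genders, p=g_p / g_p.sum()))
    eths = list(config.ethnicity_weights)
    e_p = np.array(list(config.ethnicity_weights.values()), dtype=float)
    ethnicity = str(rng.choice(eths, p=e_p / e_p.sum()))
    return Respondent(
        id=rid,
        age=age,
        education=education,
        gender=gender,
        ethnicity=ethnicity,
        latent_speed=float(rng.standard_normal()),
        inhibition_cost=float(np.exp(abs(rng.normal(0.0, config.inhibition_cost_sd)))),
        switching_cost=float(np.exp(abs(rng.normal(0.0, config.switching_cost_sd)))),
        error_proneness=float(rng.lognormal(0.0, config.error_proneness_sd)),
    )


def median_latency_ms(config: SimConfig, r: Respondent, cond: ConditionSpec,
                      cond_noise: float = 0.0) -> float:
    """Median per-item latency for respondent ``r`` in ``cond`` (ms)."""
    m = (1000.0 / config.base_rate) * config.condition_cost[cond.id]
    m *= math.exp(config.age_slope * (r.age - config.age_mean))
    m *= math.exp(-r.latent_speed * config.trait_sd)
    if cond.response_rule in (ResponseRule.OPPOSITE, ResponseRule.SWITCH):
        m *= r.inhibition_cost
    if cond.response_rule is ResponseRule.SWITCH:
        m *= r.switching_cost
    m *= math.exp(config.cond_noise_sd * cond_noise)
    return m


def error_rate(config: SimConfig, r: Respondent, cond: ConditionSpec) -> float:
    """Per-item probability of a wrong keypress."""
    return min(config.max_error_rate, config.base_error[cond.id] * r.error_proneness)


class SimulatedResponder:
    """Responder for one (respondent, condition) pair.

    Latencies and error indicators are drawn in blocks from a private
    generator, so per-item cost stays low during full-session runs.
    """

    def __init__(self, config: SimConfig, r: Respondent, cond: ConditionSpec,
                 rng: np.random.Generator, cond_noise: float = 0.0):
        self._cond = cond
        self._rng = rng
        self._median = median_latency_ms(config, r, cond, cond_noise)
        self._sigma = config.item_sd
        self._p_err = error_rate(config, r, cond)
        self._lat: np.ndarray = np.empty(0)
        self._err: np.ndarray = np.empty(0, dtype=bool)
        self._pos = 0

    def _refill(self, block: int = 64) -> None:
        if self._sigma > 0:
            self._lat = self._median * np.exp(self._rng.normal(0.0, self._sigma, block))
        else:
            self._lat = np.full(block, self._median)
        self._err = self._rng.random(block) < self._p_err
        self._pos = 0

    def respond(self, cond: ConditionSpec, phase: Phase,
                stimulus: Stimulus) -> tuple[Direction, int]:
        if self._pos >= len(self._lat):
            self._refill()
        latency = max(1, int(round(self._lat[self._pos])))
        wrong = self._err[self._pos]
        self._pos += 1
        target = required_response(cond, stimulus)
        if wrong:
            others = [d for d in DIRECTIONS if d is not target]
            target = others[int(self._rng.integers(0, 3))]
        return target, latency


class SessionResponder:
    """Dispatches to a per-condition SimulatedResponder during a session."""

    def __init__(self, config: SimConfig, r: Respondent,
                 per_condition: dict[str, SimulatedResponder]):
        self._per_condition = per_condition

    def respond(self, cond: ConditionSpec, phase: Phase,
                stimulus: Stimulus) -> tuple[Direction, int]:
        return self._per_condition[cond.id].respond(cond, phase, stimulus)


def make_responder(config: SimConfig, r: Respondent, cond: ConditionSpec,
                   rng: np.random.Generator,
                   cond_noise: float = 0.0) -> SimulatedResponder:
    """Build the stochastic responder bridging a respondent to the engine."""
    return SimulatedResponder(config, r, cond, rng, cond_noise)


@dataclass
class CohortTable:
    """Flat analysis table: one row per respondent.

    Columns: id, age, education, gender, ethnicity, k1..k6 (items
    correct), accuracy_k1..accuracy_k6, and the surrogate external
    measures.  Missing external-measure values are NaN.
    """

    data: pd.DataFrame

    SUBTESTS = tuple(c.lower() for c in CONDITION_ORDER)

    def __post_init__(self) -> None:
        for col in ("id", "age") + self.SUBTESTS:
            if col not in self.data.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        k = self.data[list(self.SUBTESTS)]
        if (k.to_numpy() < 0).any():
            raise ValueError("subtest scores must be non-negative")

    def __len__(self) -> int:
        return len(self.data)


def _session_scores_engine(config: SimConfig, r: Respondent,
                           responder_ss: np.random.SeedSequence,
                           session_seed: int) -> SessionResult:
    cond_children = responder_ss.spawn(len(CONDITION_ORDER))
    per_condition: dict[str, SimulatedResponder] = {}
    for cid, child in zip(CONDITION_ORDER, cond_children):
        crng = np.random.default_rng(child)
        w = float(crng.standard_normal())
        per_condition[cid] = SimulatedResponder(config, r, CONDITIONS[cid], crng, w)
    responder = SessionResponder(config, r, per_condition)
    return run_session(responder, VirtualClock(), session_seed, respondent_id=r.id)


def simulate_session(config: SimConfig, r: Respondent, seed: int) -> SessionResult:
    """Administer one full session to a simulated respondent.

    ``seed`` drives both the responder's latency/error draws and the
    engine's stimulus streams.
    """
    responder_ss, session_ss = np.random.SeedSequence(seed).spawn(2)
    session_seed = int(np.random.default_rng(session_ss).integers(0, 2**31 - 1))
    return _session_scores_engine(config, r, responder_ss, session_seed)


def _session_scores_analytic(config: SimConfig, r: Respondent,
                             responder_ss: np.random.SeedSequence
                             ) -> tuple[dict[str, int], dict[str, float]]:
    """Expected-count shortcut: items attempted = floor(60 s / mean latency),
    items correct binomial.  Matches the engine's score distribution up to
    the (small) within-trial timing noise."""
    scores: dict[str, int] = {}
    accuracy: dict[str, float] = {}
    cond_children = responder_ss.spawn(len(CONDITION_ORDER))
    for cid, child in zip(CONDITION_ORDER, cond_children):
        crng = np.random.default_rng(child)
        w = float(crng.standard_normal())
        cond = CONDITIONS[cid]
        median = median_latency_ms(config, r, cond, w)
        mean_latency = median * math.exp(config.item_sd ** 2 / 2.0)
        attempted = int(cond.trial_duration_ms // max(1.0, mean_latency))
        p_err = error_rate(config, r, cond)
        correct = int(crng.binomial(attempted, 1.0 - p_err)) if attempted else 0
        scores[cid.lower()] = correct
        accuracy[cid.lower()] = correct / attempted if attempted else 0.0
    return scores, accuracy


def speed_composite(config: SimConfig, ages: np.ndarray,
                    latent: np.ndarray) -> np.ndarray:
    """Standardized person-level speed advantage (higher = faster)."""
    raw = config.trait_sd * latent - config.age_slope * (ages - config.age_mean)
    sd = raw.std(ddof=1)
    return (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Simulate a full cohort and assemble the analysis table.

    All randomness descends from ``config.seed``.  In engine mode every
    respondent sits a complete session (practice gates plus six timed
    trials) through the session engine; analytic mode computes expected
    per-trial counts instead.  Surrogate external measures and optional
    MCAR missingness are appended afterwards.
    """
    root = np.random.SeedSequence(config.seed)
    demo_ss, responder_root, session_root, measure_ss = root.spawn(4)
    demo_rng = np.random.default_rng(demo_ss)
    responder_children = responder_root.spawn(config.n)
    session_seed_rng = np.random.default_rng(session_root)
    session_seeds = session_seed_rng.integers(0, 2**31 - 1, size=config.n)

    rows = []
    respondents = []
    for i in range(config.n):
        r = sample_respondent(config, demo_rng, rid=f"sim{i:05d}")
        respondents.append(r)
        row: dict = {
            "id": r.id, "age": r.age, "education": r.education,
            "gender": r.gender, "ethnicity": r.ethnicity,
        }
        if config.mode == "engine":
            session = _session_scores_engine(
                config, r, responder_children[i], int(session_seeds[i]))
            for res in session.results:
                row[res.condition.lower()] = res.items_correct
                row[f"accuracy_{res.condition.lower()}"] = res.accuracy
        else:
            scores, accuracy = _session_scores_analytic(
                config, r, responder_children[i])
            for cid in CONDITION_ORDER:
                row[cid.lower()] = scores[cid.lower()]
                row[f"accuracy_{cid.lower()}"] = accuracy[cid.lower()]
        rows.append(row)

    df = pd.DataFrame(rows)
    _append_measures(config, df, respondents, np.random.default_rng(measure_ss))
    return CohortTable(df)


def _append_measures(config: SimConfig, df: pd.DataFrame,
                     respondents: list[Respondent],
                     rng: np.random.Generator) -> None:
    n = len(df)
    if n == 0:
        for m in config.measures:
            df[m.name] = pd.Series(dtype=float)
        return
    ages = df["age"].to_numpy(dtype=float)
    latent = np.array([r.latent_speed for r in respondents])
    comp = speed_composite(config, ages, latent) if n > 1 else np.zeros(n)
    for m in config.measures:
        noise = rng.standard_normal(n)
        z = m.loading * comp + math.sqrt(max(0.0, 1.0 - m.loading ** 2)) * noise
        values = m.mean + m.sd * z
        if config.missingness:
            miss_rate = 1.0 - m.pairs_n / config.reference_n
            mask = rng.random(n) < miss_rate
            values = np.where(mask, np.nan, values)
        df[m.name] = values
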