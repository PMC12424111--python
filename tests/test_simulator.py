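"""Respondent simulator: sampling distributions, latent-trait mechanics,
cohort-level calibration properties."""

import math

import numpy as np
import pytest
from scipy import stats

import keystrokes as ks
from keystrokes.session_engine import VirtualClock, run_timed_trial
from keystrokes.simulator import (
    AGE_MAX,
    AGE_MEAN,
    AGE_MIN,
    AGE_SD,
    MEASURE_SPECS,
    SimConfig,
    _DEFAULT_CONDITION_COST,
    error_rate,
    make_responder,
    median_latency_ms,
    sample_respondent,
    simulate_cohort,
)
from keystrokes.task_model import CONDITIONS

KCOLS = [f"k{i}" for i in range(1, 7)]


def deterministic_config(**overrides) -> SimConfig:
    """All dispersions and error rates zero: the responder is exact."""
    base = dict(
        n=1, seed=0, base_rate=2.0,
        condition_cost={c: 1.0 for c in ks.CONDITION_ORDER},
        age_slope=0.0, trait_sd=0.0, item_sd=0.0, cond_noise_sd=0.0,
        inhibition_cost_sd=0.0, switching_cost_sd=0.0,
        base_error={c: 0.0 for c in ks.CONDITION_ORDER},
        error_proneness_sd=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestSampleRespondent:
    def test_age_matches_truncated_normal_oracle(self):
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(77)
        ages = np.array([sample_respondent(cfg, rng).age for _ in range(10_000)])
        a = (AGE_MIN - AGE_MEAN) / AGE_SD
        b = (AGE_MAX - AGE_MEAN) / AGE_SD
        oracle = stats.truncnorm(a, b, loc=AGE_MEAN, scale=AGE_SD)
        assert abs(ages.mean() - oracle.mean()) < 3 * oracle.std() / 100
        assert abs(ages.std(ddof=1) - oracle.std()) < 0.5
        assert ages.min() >= AGE_MIN and ages.max() <= AGE_MAX

    def test_fixed_seed_reproduces_respondent(self):
        cfg = SimConfig(seed=0)
        a = sample_respondent(cfg, np.random.default_rng(5))
        b = sample_respondent(cfg, np.random.default_rng(5))
        assert a == b

    def test_trait_invariants(self):
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(3)
        for _ in range(200):
            r = sample_respondent(cfg, rng)
            assert r.inhibition_cost >= 1 and r.switching_cost >= 1
            assert r.education >= 12
            assert r.error_proneness > 0


class TestResponderMechanics:
    def test_degenerate_config_reproduces_timing_oracle(self):
        """With every noise source at zero the responder answers every item
        correctly at the constant median latency, so each condition's score
        is the engine's closed-form count."""
        cfg = deterministic_config()
        r = sample_respondent(cfg, np.random.default_rng(1))
        for cid in ks.CONDITION_ORDER:
            cond = CONDITIONS[cid]
            assert median_latency_ms(cfg, r, cond) == pytest.approx(500.0)
            responder = make_responder(cfg, r, cond, np.random.default_rng(2))
            res = run_timed_trial(cond, responder, VirtualClock(),
                                  np.random.default_rng(3))
            assert res.items_correct == 60_000 // 500
            assert res.accuracy == 1.0

    def test_half_error_rate_gives_half_accuracy(self):
        cfg = deterministic_config(
            base_error={c: 0.5 for c in ks.CONDITION_ORDER}, max_error_rate=0.5)
        r = sample_respondent(cfg, np.random.default_rng(1))
        responder = make_responder(cfg, r, CONDITIONS["K1"],
                                   np.random.default_rng(4))
        res = run_timed_trial(CONDITIONS["K1"], responder, VirtualClock(),
                              np.random.default_rng(5))
        se = math.sqrt(0.25 / res.items_attempted)
        assert abs(res.accuracy - 0.5) < 3 * se

    def test_wrong_answers_never_match_target(self):
        cfg = deterministic_config(
            base_error={c: 1.0 for c in ks.CONDITION_ORDER}, max_error_rate=1.0)
        r = sample_respondent(cfg, np.random.default_rng(1))
        responder = make_responder(cfg, r, CONDITIONS["K3"],
                                   np.random.default_rng(6))
        res = run_timed_trial(CONDITIONS["K3"], responder, VirtualClock(),
                              np.random.default_rng(7))
        assert res.items_correct == 0

    def test_condition_cost_monotonically_slows_scoring(self):
        """Doubling the cost multiplier halves the expected item count."""
        means = []
        for cost in (1.0, 1.5, 2.0):
            cfg = deterministic_config(
                condition_cost={c: cost for c in ks.CONDITION_ORDER})
            r = sample_respondent(cfg, np.random.default_rng(1))
            responder = make_responder(cfg, r, CONDITIONS["K1"],
                                       np.random.default_rng(8))
            res = run_timed_trial(CONDITIONS["K1"], responder, VirtualClock(),
                                  np.random.default_rng(9))
            means.append(res.items_correct)
        assert means[0] > means[1] > means[2]
        assert means[2] == means[0] // 2

    def test_error_rate_is_capped(self):
        cfg = SimConfig(seed=0)
        r = sample_respondent(cfg, np.random.default_rng(1))
        capped = ks.Respondent(
            id="x", age=50, education=16, gender="female",
            ethnicity="caucasian", latent_speed=0.0, inhibition_cost=1.0,
            switching_cost=1.0, error_proneness=1000.0)
        assert error_rate(cfg, capped, CONDITIONS["K6"]) == cfg.max_error_rate


class TestCohort:
    def test_cohort_table_shape_and_columns(self, analytic_cohort):
        df = analytic_cohort.data
        assert len(df) == 400
        for col in ("id", "age", "education", "gender", "ethnicity",
                    *KCOLS, "DS", "BAI"):
            assert col in df.columns
        assert (df[KCOLS].to_numpy() >= 0).all()
        assert df["id"].is_unique

    def test_cohort_deterministic_for_fixed_seed(self):
        cfg = SimConfig(n=25, seed=42, mode="analytic")
        a = simulate_cohort(cfg).data
        b = simulate_cohort(cfg).data
        assert a.equals(b)

    def test_scores_decrease_with_age(self, analytic_cohort):
        df = analytic_cohort.data
        for k in KCOLS:
            assert df[k].corr(df["age"]) < 0

    def test_subtest_scores_strongly_intercorrelated(self, analytic_cohort):
        c = analytic_cohort.data[KCOLS].corr().to_numpy()
        off = c[~np.eye(6, dtype=bool)]
        assert off.min() > 0.6  # loose bound at n=400; calibration is
        # asserted at scale in the acceptance suite

    def test_engine_and_analytic_modes_agree_in_distribution(
            self, analytic_cohort, engine_cohort_small):
        """The analytic shortcut reproduces the engine's score level: the
        per-condition means differ by at most a few percent."""
        ma = analytic_cohort.data[KCOLS].mean()
        me = engine_cohort_small.data[KCOLS].mean()
        sd = analytic_cohort.data[KCOLS].std()
        n_eng = len(engine_cohort_small.data)
        for k in KCOLS:
            # 3 standard errors of the engine mean, plus 2% systematic slack
            tol = 3 * sd[k] / math.sqrt(n_eng) + 0.02 * ma[k]
            assert abs(ma[k] - me[k]) < tol

    def test_discriminant_measures_uncorrelated_with_scores(self):
        table = simulate_cohort(SimConfig(n=5000, seed=13, mode="analytic"))
        df = table.data
        for m in ("BDI", "BAI"):
            for k in KCOLS:
                assert abs(df[k].corr(df[m])) < 0.05

    def test_external_measure_sign_pattern(self, analytic_cohort):
        df = analytic_cohort.data
        for m in ("DS", "SS", "CD", "MR", "RDS", "OI", "CI"):
            assert df["k1"].corr(df[m]) > 0
        for m in ("TMT_A", "TMT_B", "GPT"):
            assert df["k1"].corr(df[m]) < 0

    def test_missingness_rates_match_pair_counts(self):
        table = simulate_cohort(SimConfig(n=870, seed=21, mode="analytic",
                                          missingness=True))
        df = table.data
        for spec in MEASURE_SPECS:
            target = 1.0 - spec.pairs_n / 87
            observed = df[spec.name].isna().mean()
            se = math.sqrt(max(target * (1 - target), 0.001) / 870)
            assert abs(observed - target) < 4 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n=-1)
        with pytest.raises(ValueError):
            SimConfig(mode="magic")
        with pytest.raises(ValueError):
            bad = dict(_DEFAULT_CONDITION_COST)
            bad["K6"] = 0.5  # switching cheaper than speeded
            SimConfig(condition_cost=bad)
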