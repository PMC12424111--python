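import numpy as np
import pytest

import keystrokes as ks
from keystrokes.task_model import ConditionSpec, Direction, Phase, Stimulus


class FixedLatencyResponder:
    """Always answers correctly with a fixed latency."""

    def __init__(self, latency_ms: int = 500):
        self.latency_ms = latency_ms

    def respond(self, cond, phase, stimulus):
        return ks.required_response(cond, stimulus), self.latency_ms


class ScriptedResponder:
    """Follows a correct/incorrect script (cycled), fixed latency."""

    def __init__(self, script, latency_ms: int = 500):
        self.script = list(script)
        self.latency_ms = latency_ms
        self._i = 0

    def respond(self, cond, phase, stimulus):
        ok = self.script[self._i % len(self.script)]
        self._i += 1
        target = ks.required_response(cond, stimulus)
        if not ok:
            target = next(d for d in Direction if d is not target)
        return target, self.latency_ms


class NoisyResponder:
    """Correct with probability p, seeded; fixed latency."""

    def __init__(self, p_correct: float, seed: int = 0, latency_ms: int = 500):
        self.p = p_correct
        self.rng = np.random.default_rng(seed)
        self.latency_ms = latency_ms

    def respond(self, cond, phase, stimulus):
        target = ks.required_response(cond, stimulus)
        if self.rng.random() >= self.p:
            target = next(d for d in Direction if d is not target)
        return target, self.latency_ms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def analytic_cohort():
    """Moderate cohort via the analytic score path (fast, shared)."""
    return ks.simulate_cohort(ks.SimConfig(n=400, seed=7, mode="analytic"))


@pytest.fixture(scope="session")
def engine_cohort_small():
    """Small cohort through the full session engine."""
    return ks.simulate_cohort(ks.SimConfig(n=60, seed=11, mode="engine"))


@pytest.fixture
def fixed_responder():
    return FixedLatencyResponder(500)
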