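"""Run a full KS session against any responder, human or simulated.

The engine is responder-agnostic: anything implementing the
:class:`Responder` protocol — a callback receiving (condition, phase,
stimulus) and returning (direction pressed, latency in ms) — can be
administered.  Timing is mediated by a :class:`Clock` so that simulated
sessions run instantly and deterministically on a :class:`VirtualClock`
while interactive sessions use wall time.

Scoring rules:

* stimuli are presented back to back (no inter-stimulus interval);
  the next item appears the moment a response lands;
* an item counts as attempted only if its response lands at or before
  the 60 000 ms boundary — an item still pending when time runs out is
  neither logged nor counted;
* no per-item deadline within the window;
* practice continues until the last ``practice_streak`` responses are
  all correct, up to a configurable item cap.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Protocol

import numpy as np

from .task_model import (
    CONDITION_ORDER,
    CONDITIONS,
    ConditionSpec,
    Direction,
    Phase,
    Stimulus,
    generate_stream,
    required_response,
)


class ResponderError(RuntimeError):
    """A responder failed to produce an answer mid-trial."""


class Responder(Protocol):
    def respond(
        self, cond: ConditionSpec, phase: Phase, stimulus: Stimulus
    ) -> tuple[Direction, int]:
        """Answer one stimulus; returns (key pressed, latency in ms > 0)."""
        ...


class Clock(Protocol):
    def now(self) -> float:
        """Milliseconds; monotone non-decreasing."""
        ...

    def advance(self, ms: float) -> None:
        """Advance virtual time; a no-op for real clocks."""
        ...


class VirtualClock:
    """Deterministic clock advanced explicitly by the engine."""

    def __init__(self, start_ms: float = 0.0):
        self._t = float(start_ms)

    def now(self) -> float:
        return self._t

    def advance(self, ms: float) -> None:
        if ms < 0:
            raise ValueError("cannot advance a clock backwards")
        self._t += ms


class WallClock:
    """Real time in ms; ``advance`` is a no-op (latency elapses naturally)."""

    def now(self) -> float:
        return time.monotonic() * 1000.0

    def advance(self, ms: float) -> None:  # pragma: no cover - trivial
        pass


@dataclass(frozen=True)
class TrialEvent:
    """One presented item and its response."""

    index: int
    onset_ms: float
    stimulus: Stimulus
    response: Direction | None
    latency_ms: int
    correct: bool


@dataclass(frozen=True)
class PracticeOutcome:
    events: tuple[TrialEvent, ...]
    passed: bool

    @property
    def items_administered(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SubtestResult:
    """Scores for one condition's timed trial.

    ``complete`` is False when the responder failed mid-trial;
    ``practice_passed`` is False when the practice cap was exhausted
    (the timed trial is still administered and flagged).
    """

    condition: str
    items_correct: int
    items_attempted: int
    accuracy: float
    latencies_ms: tuple[int, ...]
    events: tuple[TrialEvent, ...] = ()
    complete: bool = True
    practice_passed: bool = True


@dataclass(frozen=True)
class SessionResult:
    respondent_id: str
    seed: int
    results: tuple[SubtestResult, ...]
    started_at_ms: float = 0.0
    finished_at_ms: float = 0.0

    def __post_init__(self) -> None:
        ids = tuple(r.condition for r in self.results)
        if ids != CONDITION_ORDER:
            raise ValueError(f"session must hold results for {CONDITION_ORDER} in order, got {ids}")

    def scores(self) -> dict[str, int]:
        return {r.condition.lower(): r.items_correct for r in self.results}


def score_events(condition: str, events: Iterable[TrialEvent], *,
                 complete: bool = True, practice_passed: bool = True) -> SubtestResult:
    """Score a timed-trial event sequence.

    This is the single scoring path: the engine and the event-log replay
    both call it, so a persisted log rescores to the identical result.
    """
    events = tuple(events)
    attempted = len(events)
    correct = sum(1 for e in events if e.correct)
    accuracy = correct / attempted if attempted else 0.0
    return SubtestResult(
        condition=condition,
        items_correct=correct,
        items_attempted=attempted,
        accuracy=accuracy,
        latencies_ms=tuple(e.latency_ms for e in events),
        events=events,
        complete=complete,
        practice_passed=practice_passed,
    )


FeedbackHook = Callable[[TrialEvent, str], None]


class _BufferedStream:
    """Draws stimuli from generate_stream in blocks; order is identical to
    consuming the same generator one block at a time, and deterministic
    for a fixed generator state."""

    def __init__(self, cond: ConditionSpec, rng: np.random.Generator, block: int = 64):
        self._cond = cond
        self._rng = rng
        self._block = block
        self._buf: list[Stimulus] = []
        self._pos = 0

    def next(self) -> Stimulus:
        if self._pos >= len(self._buf):
            self._buf = generate_stream(self._cond, self._rng, self._block)
            self._pos = 0
        s = self._buf[self._pos]
        self._pos += 1
        return s


def run_practice(
    cond: ConditionSpec,
    responder: Responder,
    rng: np.random.Generator,
    max_items: int = 100,
    feedback: FeedbackHook | None = None,
) -> PracticeOutcome:
    """Administer the example trial until five-in-a-row correct.

    Presents stimuli one at a time with per-item feedback (a positive
    mark on a correct answer, the retry message otherwise) and stops at
    the first run of ``cond.practice_streak`` consecutive correct
    responses, or at ``max_items`` with ``passed=False``.
    """
    from .instructions import FEEDBACK_CORRECT_MARK, FEEDBACK_RETRY

    if max_items < cond.practice_streak:
        raise ValueError("max_items must be at least the required streak")
    events: list[TrialEvent] = []
    streak = 0
    onset = 0.0
    stream = _BufferedStream(cond, rng, block=8)
    while len(events) < max_items:
        stim = stream.next()
        direction, latency = responder.respond(cond, Phase.PRACTICE, stim)
        latency = int(latency)
        if latency <= 0:
            raise ResponderError("latency must be a positive number of milliseconds")
        ok = direction == required_response(cond, stim)
        ev = TrialEvent(len(events), onset, stim, direction, latency, ok)
        events.append(ev)
        onset += latency
        if feedback is not None:
            feedback(ev, FEEDBACK_CORRECT_MARK if ok else FEEDBACK_RETRY)
        streak = streak + 1 if ok else 0
        if streak >= cond.practice_streak:
            return PracticeOutcome(tuple(events), passed=True)
    return PracticeOutcome(tuple(events), passed=False)


def run_timed_trial(
    cond: ConditionSpec,
    responder: Responder,
    clock: Clock,
    rng: np.random.Generator,
    *,
    practice_passed: bool = True,
) -> SubtestResult:
    """Administer one 60-second timed trial and score it.

    Items advance immediately on each response and no feedback is given.
    Only responses landing at or before the duration boundary count; a
    responder failure mid-trial yields a partial result flagged
    ``complete=False``.
    """
    start = clock.now()
    deadline = start + cond.trial_duration_ms
    events: list[TrialEvent] = []
    complete = True
    stream = _BufferedStream(cond, rng, block=64)
    while clock.now() < deadline:
        stim = stream.next()
        try:
            direction, latency = responder.respond(cond, Phase.TIMED, stim)
        except ResponderError:
            complete = False
            break
        latency = int(latency)
        if latency <= 0:
            raise ResponderError("latency must be a positive number of milliseconds")
        onset = clock.now() - start
        clock.advance(latency)
        if clock.now() - start > cond.trial_duration_ms:
            break  # response landed past the boundary: not an attempt
        ok = direction == required_response(cond, stim)
        events.append(TrialEvent(len(events), onset, stim, direction, latency, ok))
    return score_events(cond.id, events, complete=complete, practice_passed=practice_passed)


def derive_streams(seed: int) -> dict[str, dict[str, np.random.Generator]]:
    """Per-condition practice/timed generators derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(CONDITION_ORDER))
    out: dict[str, dict[str, np.random.Generator]] = {}
    for cid, child in zip(CONDITION_ORDER, children):
        practice_ss, timed_ss = child.spawn(2)
        out[cid] = {
            "practice": np.random.default_rng(practice_ss),
            "timed": np.random.default_rng(timed_ss),
        }
    return out


def run_session(
    responder: Responder,
    clock: Clock,
    seed: int,
    respondent_id: str = "anonymous",
    *,
    practice_max_items: int = 100,
    feedback: FeedbackHook | None = None,
) -> SessionResult:
    """Administer all six conditions in the fixed order K1..K6.

    Each condition runs its practice gate followed by the timed trial.
    A practice-cap failure is recorded on the condition's result and the
    session continues.  One master seed derives independent per-trial
    stimulus streams, so any single trial is reproducible in isolation.
    """
    streams = derive_streams(seed)
    started = clock.now()
    results = []
    for cid in CONDITION_ORDER:
        cond = CONDITIONS[cid]
        practice = run_practice(
            cond, responder, streams[cid]["practice"], max_items=practice_max_items,
            feedback=feedback,
        )
        result = run_timed_trial(
            cond, responder, clock, streams[cid]["timed"],
            practice_passed=practice.passed,
        )
        results.append(result)
    return SessionResult(
        respondent_id=respondent_id,
        seed=seed,
        results=tuple(results),
        started_at_ms=started,
        finished_at_ms=clock.now(),
    )
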