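"""Deterministic definition of the six KeyStrokes (KS) conditions.

The KS test presents directional stimuli — an arrow glyph or the
corresponding lowercase word — and the respondent answers with one of the
four arrow keys.  The six conditions differ only in which modalities may
appear and in the rule mapping stimulus to correct key:

========  ==============  =========  ==============================
id        modalities      rule       construct
========  ==============  =========  ==============================
K1        arrows          match      response speed
K2        words           match      response speed
K3        arrows          opposite   inhibition
K4        words           opposite   inhibition
K5        arrows + words  opposite   inhibition (mixed modality)
K6        arrows + words  switch     inhibition / set-shifting
========  ==============  =========  ==============================

Under the *switch* rule the default is still "press the opposite key",
but a stimulus drawn inside a box overrides that: boxed stimuli must be
matched exactly.  Every condition runs a practice gate (five consecutive
correct answers) followed by one 60-second timed trial.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Direction(enum.Enum):
    """One of the four arrow-key directions."""

    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"

    @property
    def word(self) -> str:
        """Lowercase word form, exactly as shown in the word modality."""
        return self.value

    @property
    def glyph(self) -> str:
        """Arrow glyph shown in the arrow modality."""
        return _GLYPHS[self]


_GLYPHS = {
    Direction.UP: "↑",
    Direction.DOWN: "↓",
    Direction.LEFT: "←",
    Direction.RIGHT: "→",
}

_OPPOSITE = {
    Direction.UP: Direction.DOWN,
    Direction.DOWN: Direction.UP,
    Direction.LEFT: Direction.RIGHT,
    Direction.RIGHT: Direction.LEFT,
}

DIRECTIONS: tuple[Direction, ...] = (
    Direction.UP,
    Direction.DOWN,
    Direction.LEFT,
    Direction.RIGHT,
)


def opposite(d: Direction) -> Direction:
    """Return the paired opposite direction (up<->down, left<->right)."""
    return _OPPOSITE[d]


class Modality(enum.Enum):
    ARROW = "arrow"
    WORD = "word"


class ResponseRule(enum.Enum):
    MATCH = "match"
    OPPOSITE = "opposite"
    SWITCH = "switch"


class Phase(enum.Enum):
    PRACTICE = "practice"
    TIMED = "timed"


@dataclass(frozen=True)
class Stimulus:
    """A single presented item: a direction in some modality, optionally boxed."""

    direction: Direction
    modality: Modality
    boxed: bool = False

    def render(self) -> str:
        text = self.direction.glyph if self.modality is Modality.ARROW else self.direction.word
        return f"[{text}]" if self.boxed else text


class IllegalStimulusError(ValueError):
    """Raised when a stimulus is not legal under a condition's rules."""


@dataclass(frozen=True)
class ConditionSpec:
    """Rules of one KS subtest.

    ``boxed_fraction`` is the probability that a generated stimulus is
    boxed; it must be zero unless the response rule is SWITCH.
    ``trial_duration_ms`` and ``practice_streak`` are the same for every
    condition (60 s; five in a row) but kept on the spec so alternative
    forms remain expressible.
    """

    id: str
    modalities: tuple[Modality, ...]
    response_rule: ResponseRule
    boxed_fraction: float = 0.0
    trial_duration_ms: int = 60_000
    practice_streak: int = 5

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError(f"{self.id}: at least one modality required")
        if self.boxed_fraction and self.response_rule is not ResponseRule.SWITCH:
            raise ValueError(f"{self.id}: boxed stimuli only occur under the SWITCH rule")
        if not 0.0 <= self.boxed_fraction <= 1.0:
            raise ValueError(f"{self.id}: boxed_fraction must lie in [0, 1]")

    def is_legal(self, s: Stimulus) -> bool:
        if s.modality not in self.modalities:
            return False
        if s.boxed and self.response_rule is not ResponseRule.SWITCH:
            return False
        return True


#: Default boxed proportion for the switching condition.  The instructions
#: describe boxed items as the minority ("for many of the trials, you should
#: do the same thing you just did"); one quarter keeps the switch demand real
#: without inverting the prepotent rule.
DEFAULT_BOXED_FRACTION = 0.25

CONDITION_ORDER: tuple[str, ...] = ("K1", "K2", "K3", "K4", "K5", "K6")

CONDITIONS: dict[str, ConditionSpec] = {
    "K1": ConditionSpec("K1", (Modality.ARROW,), ResponseRule.MATCH),
    "K2": ConditionSpec("K2", (Modality.WORD,), ResponseRule.MATCH),
    "K3": ConditionSpec("K3", (Modality.ARROW,), ResponseRule.OPPOSITE),
    "K4": ConditionSpec("K4", (Modality.WORD,), ResponseRule.OPPOSITE),
    "K5": ConditionSpec("K5", (Modality.ARROW, Modality.WORD), ResponseRule.OPPOSITE),
    "K6": ConditionSpec(
        "K6",
        (Modality.ARROW, Modality.WORD),
        ResponseRule.SWITCH,
        boxed_fraction=DEFAULT_BOXED_FRACTION,
    ),
}


def required_response(cond: ConditionSpec, s: Stimulus) -> Direction:
    """The correct key for stimulus ``s`` under condition ``cond``.

    MATCH presses the displayed direction; OPPOSITE presses its pair;
    SWITCH presses the displayed direction when the stimulus is boxed
    and the opposite otherwise.
    """
    if not cond.is_legal(s):
        raise IllegalStimulusError(
            f"stimulus {s!r} is not legal under condition {cond.id} "
            f"(modalities {[m.value for m in cond.modalities]}, rule {cond.response_rule.value})"
        )
    if cond.response_rule is ResponseRule.MATCH:
        return s.direction
    if cond.response_rule is ResponseRule.OPPOSITE:
        return opposite(s.direction)
    # SWITCH: boxed items override the prepotent opposite rule
    return s.direction if s.boxed else opposite(s.direction)


def legal_stimuli(cond: ConditionSpec) -> list[Stimulus]:
    """Every stimulus the condition can present (at most 16)."""
    out = []
    for d in DIRECTIONS:
        for m in cond.modalities:
            out.append(Stimulus(d, m, False))
            if cond.response_rule is ResponseRule.SWITCH and cond.boxed_fraction > 0:
                out.append(Stimulus(d, m, True))
    return out


def generate_stream(cond: ConditionSpec, rng: np.random.Generator, n: int) -> list[Stimulus]:
    """Draw ``n`` i.i.d. stimuli for ``cond``.

    Direction is uniform over the four directions, modality uniform over the
    condition's allowed modalities, and the boxed flag Bernoulli with the
    condition's boxed fraction.  Reproducible given the generator state;
    immediate repeats are permitted.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    dirs = rng.integers(0, 4, size=n)
    mods = rng.integers(0, len(cond.modalities), size=n)
    if cond.boxed_fraction > 0:
        boxed = rng.random(n) < cond.boxed_fraction
    else:
        boxed = np.zeros(n, dtype=bool)
    return [
        Stimulus(DIRECTIONS[dirs[i]], cond.modalities[mods[i]], bool(boxed[i]))
        for i in range(n)
    ]
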