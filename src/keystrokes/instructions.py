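"""Instruction and feedback text shown to respondents.

The wording is fixed per condition and phase: an example-trial prompt
shown before the practice gate, and a timed-trial prompt shown once the
gate is passed.  Curly quotation marks in the source material are
normalised to plain ASCII quotes; arrow glyphs are kept as Unicode.
"""

from __future__ import annotations

from .task_model import ConditionSpec, Phase

#: Retry message shown during practice after an incorrect answer.
FEEDBACK_RETRY = (
    "That's not quite right. Try again. "
    "Press the key you see displayed on the screen"
)

#: Marks shown during practice feedback.
FEEDBACK_CORRECT_MARK = "✓"
FEEDBACK_INCORRECT_MARK = "x"

_PRACTICE: dict[str, str] = {
    "K1": (
        "This is a test designed to measure your response time. "
        "Let's try some examples. Please press the key you see on the screen."
    ),
    "K2": (
        "This is a similar test designed to measure your response time. "
        "Let's try some examples. Please press the key that corresponds to "
        "the word you see on the screen."
    ),
    "K3": (
        "This test is like the one you just finished, but slightly different. "
        "You are to press the opposite directional key than the one you see, "
        "ignoring the key that is on the screen. Let's try some examples."
    ),
    "K4": (
        "This test is like the one you just finished, but slightly different. "
        "You are to press the opposite directional key than the word you see "
        "on the screen. Let's do some examples."
    ),
    "K5": (
        "This test is just like the two you just completed, but this time you "
        "will see both symbols and words. You are to press the opposite "
        "directional key or key corresponding to a word than the one you see "
        "flash on the screen. Let's do some examples."
    ),
    "K6": (
        "This time, for many of the trials, you should do the same thing you "
        "just did: Press the opposite directional symbol (or word) that is "
        "displayed. But if a symbol (or word) is inside a box, you should "
        "match the symbol (or word) exactly. Let's practice."
    ),
}

_TIMED: dict[str, str] = {
    "K1": (
        "Good! ↑ ↓ ← → are the only symbols you will see on this test. "
        "When ready, you are to press the key you see on the screen. "
        "Work as quickly as you can. You will have 60 s to perform the trial. "
        'Try not to make mistakes. Hit "spacebar" when ready.'
    ),
    "K2": (
        "Good! Up, Down, Left, Right are the only words you will see on this "
        "test. When ready, you are to press the key that corresponds to the "
        "word you see on the screen. Work as quickly as you can. "
        "You will have 60 s to perform the trial. "
        'Try not to make mistakes. Hit "spacebar" when ready.'
    ),
    "K3": (
        "Good! ↑ ↓ ← → are the only symbols you will see on this test. "
        "When ready, you are to press the opposite directional key than the "
        "one you see, ignoring the key that is on the screen. "
        "Work as quickly as you can. You will have 60 s to perform the trial. "
        'Try not to make mistakes. Hit "spacebar" when ready.'
    ),
    "K4": (
        "Good! Up, Down, Left, and Right are the only words you will see on "
        "this test. When ready, you are to press the opposite directional key "
        "that corresponds to the word you see flash on the screen. "
        "Work as quickly as you can. You will have 60 s to perform the trial. "
        'Try not to make mistakes. Hit "spacebar" when ready.'
    ),
    "K5": (
        "Good! Up, Down, Left, Right, ↑ ↓ ← → are the only words or symbols "
        "you will see on this test. When ready, you are to press the opposite "
        "directional key or key corresponding to a word than the one you see "
        "on the screen. Work as quickly as you can. "
        "You will have 60 s to perform the trial. "
        'Try not to make mistakes. Hit "spacebar" when ready.'
    ),
    "K6": (
        "Good! Up, Down, Left, Right, ↑ ↓ ← → are the only words or symbols "
        "you will see on this test. When ready, you are to press the opposite "
        "directional key or key corresponding to a word or match the "
        "symbol/word exactly if it is in a box. Work as quickly as you can. "
        "You will have 60 s to perform the trial. "
        'Try not to make mistakes. Hit "spacebar" when ready.'
    ),
}


def instruction_text(cond: ConditionSpec, phase: Phase) -> str:
    """Verbatim instruction string for a condition and phase."""
    table = _PRACTICE if phase is Phase.PRACTICE else _TIMED
    try:
        return table[cond.id]
    except KeyError:
        raise KeyError(f"no instruction text for condition {cond.id!r}") from None
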