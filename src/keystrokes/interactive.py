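"""Interactive terminal administration: arrow keys answer, spacebar starts.

POSIX-only (termios raw mode).  The responder measures real keypress
latency around the blocking read; non-arrow keys during a timed trial
are ignored and not logged as attempts.  Ctrl-C aborts the session.
"""

from __future__ import annotations

import sys
import time

from .instructions import FEEDBACK_CORRECT_MARK, FEEDBACK_RETRY
from .session_engine import ResponderError, TrialEvent, WallClock, run_session
from .task_model import ConditionSpec, Direction, Phase, Stimulus
from .instructions import instruction_text

_ARROW_SEQ = {
    "A": Direction.UP,
    "B": Direction.DOWN,
    "C": Direction.RIGHT,
    "D": Direction.LEFT,
}


def _read_key() -> str:
    """Read one keypress in raw mode; arrow keys return 'up'/'down'/...,
    other keys return the raw character."""
    import termios
    import tty

    fd = sys.stdin.fileno()
    old = termios.tcgetattr(fd)
    try:
        tty.setraw(fd)
        ch = sys.stdin.read(1)
        if ch == "\x1b":  # escape sequence; arrows are ESC [ A..D
            rest = sys.stdin.read(2)
            if len(rest) == 2 and rest[0] == "[" and rest[1] in _ARROW_SEQ:
                return _ARROW_SEQ[rest[1]].value
            return "escape"
        if ch == "\x03":
            raise KeyboardInterrupt
        return ch
    finally:
        termios.tcsetattr(fd, termios.TCSADRAIN, old)


def _wait_for_spacebar() -> None:
    while _read_key() != " ":
        pass


class TerminalResponder:
    """Presents stimuli on stdout and reads arrow-key answers."""

    def __init__(self) -> None:
        self._last_condition: str | None = None
        self._last_phase: Phase | None = None

    def respond(self, cond: ConditionSpec, phase: Phase,
                stimulus: Stimulus) -> tuple[Direction, int]:
        if (cond.id, phase) != (self._last_condition, self._last_phase):
            print()
            print(instruction_text(cond, phase))
            if phase is Phase.TIMED:
                _wait_for_spacebar()
            self._last_condition, self._last_phase = cond.id, phase
        sys.stdout.write(f"\r   {stimulus.render()}    ")
        sys.stdout.flush()
        start = time.monotonic()
        while True:
            key = _read_key()
            if key in (d.value for d in Direction):
                latency = max(1, int((time.monotonic() - start) * 1000))
                return Direction(key), latency
            # non-arrow keys are ignored, not logged as attempts


def practice_feedback(event: TrialEvent, message: str) -> None:
    if event.correct:
        print(f"  {FEEDBACK_CORRECT_MARK}")
    else:
        print(f"  x  {FEEDBACK_RETRY}")


def administer(seed: int, respondent_id: str = "anonymous"):
    """Run a live session in the terminal and return the SessionResult."""
    if not sys.stdin.isatty():
        raise ResponderError("interactive administration requires a terminal")
    responder = TerminalResponder()
    return run_session(
        responder, WallClock(), seed, respondent_id=respondent_id,
        feedback=practice_feedback,
    )
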