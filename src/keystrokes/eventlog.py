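"""JSON Lines event logs: one header record, then one record per item.

The log is append-safe (each record is a complete JSON object on its
own line), which matters during live administration.  Replay rescores
the persisted events through the same scoring path as the engine, so a
round trip reproduces every SubtestResult exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterator

from . import __version__
from .session_engine import (
    SessionResult,
    SubtestResult,
    TrialEvent,
    score_events,
)
from .task_model import CONDITION_ORDER, Direction, Modality, Stimulus


def _event_record(condition: str, phase: str, e: TrialEvent) -> dict:
    return {
        "type": "event",
        "condition": condition,
        "phase": phase,
        "index": e.index,
        "onset_ms": e.onset_ms,
        "direction": e.stimulus.direction.value,
        "modality": e.stimulus.modality.value,
        "boxed": e.stimulus.boxed,
        "response": e.response.value if e.response is not None else None,
        "latency_ms": e.latency_ms,
        "correct": e.correct,
    }


def _event_from_record(rec: dict) -> TrialEvent:
    stim = Stimulus(
        Direction(rec["direction"]), Modality(rec["modality"]), bool(rec["boxed"])
    )
    resp = Direction(rec["response"]) if rec["response"] is not None else None
    return TrialEvent(
        index=rec["index"],
        onset_ms=rec["onset_ms"],
        stimulus=stim,
        response=resp,
        latency_ms=rec["latency_ms"],
        correct=rec["correct"],
    )


def write_session(session: SessionResult, path: str | Path, *, config_hash: str = "") -> None:
    """Write a session's timed-trial events as JSONL with a header record."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_session_fh(session, fh, config_hash=config_hash)


def _write_session_fh(session: SessionResult, fh: IO[str], *, config_hash: str = "") -> None:
    header = {
        "type": "header",
        "respondent_id": session.respondent_id,
        "seed": session.seed,
        "config_hash": config_hash,
        "version": __version__,
        "started_at_ms": session.started_at_ms,
        "finished_at_ms": session.finished_at_ms,
    }
    fh.write(json.dumps(header, sort_keys=True) + "\n")
    for result in session.results:
        meta = {
            "type": "subtest",
            "condition": result.condition,
            "complete": result.complete,
            "practice_passed": result.practice_passed,
        }
        fh.write(json.dumps(meta, sort_keys=True) + "\n")
        for e in result.events:
            fh.write(json.dumps(_event_record(result.condition, "timed", e), sort_keys=True) + "\n")


def _records(path: Path) -> Iterator[dict]:
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def read_session(path: str | Path) -> SessionResult:
    """Reconstruct a session by rescoring the persisted event log."""
    path = Path(path)
    header: dict | None = None
    flags: dict[str, dict] = {}
    events: dict[str, list[TrialEvent]] = {cid: [] for cid in CONDITION_ORDER}
    for rec in _records(path):
        if rec["type"] == "header":
            header = rec
        elif rec["type"] == "subtest":
            flags[rec["condition"]] = rec
        elif rec["type"] == "event":
            events[rec["condition"]].append(_event_from_record(rec))
        else:
            raise ValueError(f"unknown record type {rec['type']!r} in {path}")
    if header is None:
        raise ValueError(f"{path}: no header record found")
    results: list[SubtestResult] = []
    for cid in CONDITION_ORDER:
        meta = flags.get(cid, {"complete": True, "practice_passed": True})
        results.append(
            score_events(
                cid,
                events[cid],
                complete=meta["complete"],
                practice_passed=meta["practice_passed"],
            )
        )
    return SessionResult(
        respondent_id=header["respondent_id"],
        seed=header["seed"],
        results=tuple(results),
        started_at_ms=header.get("started_at_ms", 0.0),
        finished_at_ms=header.get("finished_at_ms", 0.0),
    )
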