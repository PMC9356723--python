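"""Keystroke session data model and JSON-Lines I/O.

A typing session is a nested variable-length record of one task: ordered key
events (press/release times in milliseconds from session start, keyboard
zone, key-type category, and — on touchscreens — the tap offset from the
target key centre in key-width units), a log of assisted-typing events
(autocorrect firings and word-suggestion uses, touchscreen only), and free
session context.  No letter identities are stored anywhere: the model is
content-agnostic by construction.

Sessions are serialized one JSON object per line so that logs can be
streamed and appended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

KEY_TYPES = (
    "alphanumeric",
    "space",
    "enter",
    "punctuation",
    "modifier",
    "emoji",
    "backspace",
)

ASSISTED_KINDS = ("autocorrect", "word_suggestion")

#: task identifier -> device it runs on
TASKS = {
    "mec_copy": "mechanical",
    "mec_des": "mechanical",
    "tch_copy": "touchscreen",
    "tch_conv": "touchscreen",
}

DEVICES = ("mechanical", "touchscreen")


class SessionValidationError(ValueError):
    """A session violates a structural invariant."""


class SessionParseError(ValueError):
    """A JSONL line could not be parsed."""


@dataclass(frozen=True)
class KeyEvent:
    """One keystroke: press/release millisecond timestamps, keyboard zone,
    key-type category and, for touchscreen sessions, the signed tap offset
    ``(dx, dy)`` from the target key centre in key-width units."""

    press_time: float
    release_time: float
    zone: int
    key_type: str
    tap_offset: tuple[float, float] | None = None


@dataclass(frozen=True)
class AssistedEvent:
    """An autocorrect or word-suggestion event fired after keystroke
    ``position`` at ``event_time`` milliseconds."""

    event_time: float
    kind: str
    position: int


@dataclass(frozen=True)
class SessionContext:
    start_time: str = ""
    app: str = ""
    device_descriptor: str = ""


@dataclass(frozen=True)
class TypingSession:
    """The raw keystroke tensor of one task performed by one subject."""

    session_id: str
    subject_id: str
    task_id: str
    device: str
    events: tuple[KeyEvent, ...] = ()
    assisted_events: tuple[AssistedEvent, ...] = ()
    context: SessionContext = field(default_factory=SessionContext)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "assisted_events", tuple(self.assisted_events))


def validate_session(session: TypingSession) -> list[str]:
    """Return a list of invariant-violation descriptions (empty if valid).

    Violations name the rule broken and the offending event index; they are
    returned, never raised, so callers can collect a full report.
    """
    v: list[str] = []
    if session.task_id not in TASKS:
        v.append(f"unknown task_id {session.task_id!r}")
    if session.device not in DEVICES:
        v.append(f"unknown device {session.device!r}")
    if session.task_id in TASKS and session.device in DEVICES:
        if TASKS[session.task_id] != session.device:
            v.append(
                f"task {session.task_id!r} requires device "
                f"{TASKS[session.task_id]!r}, got {session.device!r}"
            )
    touch = session.device == "touchscreen"
    prev_press = None
    for i, ev in enumerate(session.events):
        if ev.key_type not in KEY_TYPES:
            v.append(f"event {i}: unknown key_type {ev.key_type!r}")
        if ev.press_time < 0:
            v.append(f"event {i}: press_time ≥ 0 violated")
        if ev.release_time < ev.press_time:
            v.append(f"event {i}: release_time ≥ press_time violated")
        if prev_press is not None and ev.press_time < prev_press:
            v.append(f"event {i}: events not sorted by press_time")
            prev_press = ev.press_time  # report only the first break per run
        else:
            prev_press = ev.press_time
        if ev.tap_offset is not None and not touch:
            v.append(f"event {i}: tap_offset present on mechanical device")
    if not touch and session.assisted_events:
        v.append("assisted_events present on mechanical device")
    for j, ae in enumerate(session.assisted_events):
        if ae.kind not in ASSISTED_KINDS:
            v.append(f"assisted event {j}: unknown kind {ae.kind!r}")
    return v


def _session_to_dict(session: TypingSession) -> dict:
    d = asdict(session)
    # tuples serialize as lists; key order is stable for byte-identical output
    return d


def _session_from_dict(d: dict) -> TypingSession:
    events = tuple(
        KeyEvent(
            press_time=e["press_time"],
            release_time=e["release_time"],
            zone=e["zone"],
            key_type=e["key_type"],
            tap_offset=tuple(e["tap_offset"]) if e.get("tap_offset") is not None else None,
        )
        for e in d.get("events", [])
    )
    assisted = tuple(
        AssistedEvent(
            event_time=a["event_time"], kind=a["kind"], position=a["position"]
        )
        for a in d.get("assisted_events", [])
    )
    ctx = d.get("context", {}) or {}
    return TypingSession(
        session_id=d["session_id"],
        subject_id=d["subject_id"],
        task_id=d["task_id"],
        device=d["device"],
        events=events,
        assisted_events=assisted,
        context=SessionContext(
            start_time=ctx.get("start_time", ""),
            app=ctx.get("app", ""),
            device_descriptor=ctx.get("device_descriptor", ""),
        ),
    )


def read_sessions(path: str | Path) -> list[TypingSession]:
    """Read and validate typing sessions from a JSON-Lines file.

    Raises :class:`SessionParseError` naming the line number on malformed
    JSON, and :class:`SessionValidationError` naming the session and rule on
    an invariant violation.
    """
    sessions: list[TypingSession] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionParseError(f"line {lineno}: malformed JSON ({exc})") from exc
            try:
                s = _session_from_dict(d)
            except (KeyError, TypeError) as exc:
                raise SessionParseError(f"line {lineno}: missing field ({exc})") from exc
            violations = validate_session(s)
            if violations:
                raise SessionValidationError(
                    f"session {s.session_id!r}: " + "; ".join(violations)
                )
            sessions.append(s)
    return sessions


def write_sessions(sessions: Iterable[TypingSession], path: str | Path) -> None:
    """Write sessions as one JSON object per line.

    ``read_sessions(write_sessions(x))`` reproduces ``x`` field-for-field;
    floats round-trip exactly (json preserves full double precision).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for s in sessions:
            fh.write(json.dumps(_session_to_dict(s), separators=(",", ":")))
            fh.write("\n")


def sessions_by_subject(
    sessions: Sequence[TypingSession],
) -> dict[str, list[TypingSession]]:
    """Group sessions by subject, preserving input order."""
    out: dict[str, list[TypingSession]] = {}
    for s in sessions:
        out.setdefault(s.subject_id, []).append(s)
    return out
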