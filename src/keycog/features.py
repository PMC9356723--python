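"""Content-agnostic typing features: keystroke, language and precision families.

Each typing session is reduced to named statistics from three families:

* **keystroke** — timing of press/release events: hold times
  (release − press of one key), flight times (press of the next key −
  release of the previous one, negative under rollover), summarized by
  location/spread/percentile statistics, the fraction of long pauses, the
  fraction of negative flights, and the overall keystroke rate;
* **language** — text structure without text content: word lengths from
  runs of alphanumeric key types between delimiter keys
  (space/enter/punctuation), punctuation usage, enter usage;
* **precision** — error-correction and motor accuracy: backspace usage
  and, on touchscreens, tap-offset magnitude and assisted-typing
  (autocorrect / word-suggestion) rates.

The full feature vector concatenates the applicable families over the four
tasks in a fixed catalogue order, identical for every subject; slots for
tasks a subject did not perform are missing-valued (NaN).  Statistics that
are undefined for a device (tap offsets on a mechanical keyboard) have no
catalogue slot at all.
"""

from __future__ import annotations

import hashlib
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sessions import TASKS, TypingSession

#: flights longer than this many milliseconds count as pauses
DEFAULT_PAUSE_THRESHOLD_MS = 500.0

FAMILIES = ("keystroke", "language", "precision")

_KEYSTROKE_STATS = (
    "hold_mean", "hold_median", "hold_sd", "hold_iqr", "hold_p05", "hold_p95",
    "flight_mean", "flight_median", "flight_sd", "flight_iqr", "flight_p05",
    "flight_p95", "pause_frac", "neg_flight_frac", "keys_per_sec",
)
_LANGUAGE_STATS = (
    "word_count", "word_len_mean", "word_len_sd", "word_len_max",
    "punct_per_word", "enter_count", "delimiter_frac",
)
_PRECISION_STATS_COMMON = ("backspace_frac",)
_PRECISION_STATS_TOUCH = (
    "tap_mag_mean", "tap_mag_sd", "autocorrect_per100", "suggestion_per100",
)


def feature_catalogue() -> list[str]:
    """The fixed, ordered feature-name catalogue (family.task.statistic)."""
    names: list[str] = []
    for task, device in TASKS.items():
        for stat in _KEYSTROKE_STATS:
            names.append(f"keystroke.{task}.{stat}")
        for stat in _LANGUAGE_STATS:
            names.append(f"language.{task}.{stat}")
        prec = _PRECISION_STATS_COMMON + (
            _PRECISION_STATS_TOUCH if device == "touchscreen" else ()
        )
        for stat in prec:
            names.append(f"precision.{task}.{stat}")
    return names


def catalogue_hash() -> str:
    """SHA-256 of the catalogue; pins name set and order across versions."""
    return hashlib.sha256(",".join(feature_catalogue()).encode()).hexdigest()


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split ``family.task.statistic``."""
    family, task, stat = name.split(".", 2)
    return family, task, stat


def hold_times(session: TypingSession) -> list[float]:
    """Per-key hold durations (ms), order preserved."""
    return [ev.release_time - ev.press_time for ev in session.events]


def flight_times(session: TypingSession) -> list[float]:
    """Release-to-next-press intervals (ms); negative under rollover typing.

    Empty for sessions with fewer than two events.
    """
    evs = session.events
    return [evs[k + 1].press_time - evs[k].release_time for k in range(len(evs) - 1)]


def _stats_block(values: Sequence[float], prefix: str) -> dict[str, float]:
    out: dict[str, float] = {}
    arr = np.asarray(values, dtype=float)
    n = arr.size
    out[f"{prefix}_mean"] = float(arr.mean()) if n >= 1 else math.nan
    out[f"{prefix}_median"] = float(np.median(arr)) if n >= 1 else math.nan
    out[f"{prefix}_sd"] = float(arr.std(ddof=1)) if n >= 2 else math.nan
    if n >= 2:
        q75, q25 = np.percentile(arr, [75, 25])
        out[f"{prefix}_iqr"] = float(q75 - q25)
    else:
        out[f"{prefix}_iqr"] = math.nan
    out[f"{prefix}_p05"] = float(np.percentile(arr, 5)) if n >= 1 else math.nan
    out[f"{prefix}_p95"] = float(np.percentile(arr, 95)) if n >= 1 else math.nan
    return out


def keystroke_family(
    session: TypingSession,
    pause_threshold_ms: float = DEFAULT_PAUSE_THRESHOLD_MS,
) -> dict[str, float]:
    """Timing statistics of hold and flight times plus rate features."""
    holds = hold_times(session)
    flights = flight_times(session)
    out = _stats_block(holds, "hold")
    out.update(_stats_block(flights, "flight"))
    nf = len(flights)
    out["pause_frac"] = (
        sum(f > pause_threshold_ms for f in flights) / nf if nf else math.nan
    )
    out["neg_flight_frac"] = sum(f < 0 for f in flights) / nf if nf else math.nan
    if session.events:
        span_s = (session.events[-1].release_time - session.events[0].press_time) / 1000.0
        out["keys_per_sec"] = len(session.events) / span_s if span_s > 0 else math.nan
    else:
        out["keys_per_sec"] = math.nan
    return out


_DELIMITERS = {"space", "enter", "punctuation"}


def _word_lengths(session: TypingSession) -> tuple[list[int], int, int, int]:
    """Segment key-type runs into word lengths.

    Words are maximal runs of alphanumeric keys closed by a delimiter
    (space, enter or punctuation) or by the end of the session.  A backspace
    removes the most recent character from the current word count (never
    below zero); modifier and emoji keys are transparent.  Returns
    (word_lengths, punctuation_count, enter_count, delimiter_count).
    """
    lengths: list[int] = []
    cur = 0
    n_punct = n_enter = n_delim = 0
    for ev in session.events:
        kt = ev.key_type
        if kt == "alphanumeric":
            cur += 1
        elif kt == "backspace":
            cur = max(0, cur - 1)
        elif kt in _DELIMITERS:
            n_delim += 1
            if kt == "punctuation":
                n_punct += 1
            elif kt == "enter":
                n_enter += 1
            if cur > 0:
                lengths.append(cur)
                cur = 0
        # modifier / emoji: transparent to segmentation
    if cur > 0:
        lengths.append(cur)
    return lengths, n_punct, n_enter, n_delim


def language_family(session: TypingSession) -> dict[str, float]:
    """Word-structure statistics from key-type categories only."""
    lengths, n_punct, n_enter, n_delim = _word_lengths(session)
    n_words = len(lengths)
    n_events = len(session.events)
    arr = np.asarray(lengths, dtype=float)
    return {
        "word_count": float(n_words),
        "word_len_mean": float(arr.mean()) if n_words >= 1 else math.nan,
        "word_len_sd": float(arr.std(ddof=1)) if n_words >= 2 else math.nan,
        "word_len_max": float(arr.max()) if n_words >= 1 else math.nan,
        "punct_per_word": n_punct / n_words if n_words >= 1 else math.nan,
        "enter_count": float(n_enter),
        "delimiter_frac": n_delim / n_events if n_events else math.nan,
    }


def precision_family(session: TypingSession) -> dict[str, float]:
    """Backspace usage plus, on touchscreens, tap accuracy and
    assisted-typing rates (events per 100 keystrokes)."""
    n_events = len(session.events)
    n_back = sum(ev.key_type == "backspace" for ev in session.events)
    out: dict[str, float] = {
        "backspace_frac": n_back / n_events if n_events else math.nan
    }
    if session.device == "touchscreen":
        mags = [
            math.hypot(ev.tap_offset[0], ev.tap_offset[1])
            for ev in session.events
            if ev.tap_offset is not None
        ]
        marr = np.asarray(mags, dtype=float)
        out["tap_mag_mean"] = float(marr.mean()) if marr.size >= 1 else math.nan
        out["tap_mag_sd"] = float(marr.std(ddof=1)) if marr.size >= 2 else math.nan
        n_auto = sum(a.kind == "autocorrect" for a in session.assisted_events)
        n_sugg = sum(a.kind == "word_suggestion" for a in session.assisted_events)
        out["autocorrect_per100"] = 100.0 * n_auto / n_events if n_events else math.nan
        out["suggestion_per100"] = 100.0 * n_sugg / n_events if n_events else math.nan
    return out


class AmbiguousSessionsError(ValueError):
    """A subject supplied two sessions for the same task."""


def build_feature_vector(
    sessions: Iterable[TypingSession],
    pause_threshold_ms: float = DEFAULT_PAUSE_THRESHOLD_MS,
) -> pd.Series:
    """Reduce a subject's available task sessions (0–4, at most one per
    task) to the fixed catalogue order; absent tasks yield NaN slots."""
    by_task: dict[str, TypingSession] = {}
    for s in sessions:
        if s.task_id in by_task:
            raise AmbiguousSessionsError(f"two sessions for task {s.task_id!r}")
        by_task[s.task_id] = s
    values: dict[str, float] = {name: math.nan for name in feature_catalogue()}
    for task, sess in by_task.items():
        for stat, v in keystroke_family(sess, pause_threshold_ms).items():
            values[f"keystroke.{task}.{stat}"] = v
        for stat, v in language_family(sess).items():
            values[f"language.{task}.{stat}"] = v
        for stat, v in precision_family(sess).items():
            values[f"precision.{task}.{stat}"] = v
    return pd.Series(values, index=feature_catalogue(), dtype=float)


def feature_frame(
    sessions: Sequence[TypingSession],
    pause_threshold_ms: float = DEFAULT_PAUSE_THRESHOLD_MS,
) -> pd.DataFrame:
    """One row per subject, columns in catalogue order."""
    from .sessions import sessions_by_subject

    rows = {
        sid: build_feature_vector(group, pause_threshold_ms)
        for sid, group in sessions_by_subject(sessions).items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.reindex(columns=feature_catalogue())
    frame.index.name = "subject_id"
    return frame
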