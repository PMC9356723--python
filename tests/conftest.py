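import pytest

from keycog.sessions import KeyEvent, SessionContext, TypingSession


@pytest.fixture
def worked_session() -> TypingSession:
    """Hand-constructed 6-event touchscreen session with one rollover
    flight, a backspace-corrected word, and known tap offsets.

    holds   = [80, 90, 80, 60, 80, 100]
    flights = [120, -30, 160, 140, 120]
    words   = [2, 1]   (3 alphanumerics − 1 backspace, then 1 after space)
    """
    ev = [
        KeyEvent(0, 80, 1, "alphanumeric", (0.3, 0.4)),
        KeyEvent(200, 290, 2, "alphanumeric", (0.0, 0.0)),
        KeyEvent(260, 340, 3, "alphanumeric", (0.0, 0.0)),
        KeyEvent(500, 560, 4, "backspace", (0.0, 0.0)),
        KeyEvent(700, 780, 5, "space", (0.0, 0.0)),
        KeyEvent(900, 1000, 6, "alphanumeric", (0.6, 0.8)),
    ]
    return TypingSession(
        session_id="w1",
        subject_id="subjA",
        task_id="tch_copy",
        device="touchscreen",
        events=tuple(ev),
        context=SessionContext(start_time="2021-01-01T00:00:00Z"),
    )


@pytest.fixture
def two_event_session() -> TypingSession:
    """Worked two-event mechanical session: holds [80, 90], flight [120]."""
    return TypingSession(
        session_id="s2",
        subject_id="subjB",
        task_id="mec_copy",
        device="mechanical",
        events=(
            KeyEvent(0, 80, 1, "alphanumeric"),
            KeyEvent(200, 290, 2, "alphanumeric"),
        ),
    )
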