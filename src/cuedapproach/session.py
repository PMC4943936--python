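"""Session event logs, trial tables, and on-disk formats.

An operant session is a stream of millisecond-stamped events: cue onsets and
offsets (two auditory cues predicting large or small sucrose rewards),
photobeam receptacle entries and exits, and reward deliveries. Reward is
contingent on entering the receptacle while the cue is on (up to 5 s), at
which point the cue terminates.

On disk a session is a directory with ``events.csv`` (columns
``t_ms,kind,payload``; integer-millisecond timestamps make round-trips
bit-exact), optionally ``tracking.csv`` (one row per video frame, columns
``frame,red_x,red_y,green_x,green_y`` in pixels, blank cells = LED not
tracked), and a ``session.json`` sidecar with the session metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "SessionEvents",
    "TrialRecord",
    "TrackingTrace",
    "EventValidationError",
    "CUE_ON",
    "CUE_OFF",
    "ENTRY",
    "EXIT",
    "REWARD",
    "read_events",
    "write_events",
    "read_tracking",
    "write_tracking",
    "read_session",
    "write_session",
    "build_trial_table",
    "trials_to_frame",
]

CUE_ON = "CUE_ON"
CUE_OFF = "CUE_OFF"
ENTRY = "ENTRY"
EXIT = "EXIT"
REWARD = "REWARD"
_KINDS = {CUE_ON, CUE_OFF, ENTRY, EXIT, REWARD}

CUE_WINDOW = 5.0  # seconds; maximum cue presentation


class EventValidationError(ValueError):
    """Raised when an event stream breaks a structural invariant."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Event:
    """One timestamped event. ``payload`` is the cue type for CUE_ON
    ("LARGE"/"SMALL"), the volume in microlitres for REWARD, else ``None``."""

    t: float
    kind: str
    payload: object = None

    @property
    def t_ms(self) -> int:
        return round(self.t * 1000)


@dataclass
class SessionEvents:
    """Ordered event stream of a single session."""

    session_id: str
    condition_label: str
    duration: float
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Check ordering, bounds, 1-ms quantisation and alternation rules."""
        prev_t = 0.0
        cue_on = False
        inside = False
        for i, ev in enumerate(self.events, start=1):
            if ev.kind not in _KINDS:
                raise EventValidationError(f"unknown event kind {ev.kind!r}", i)
            if ev.t < prev_t - 1e-12:
                raise EventValidationError("timestamps must be non-decreasing", i)
            if ev.t < 0 or ev.t > self.duration + 1e-9:
                raise EventValidationError("timestamp outside [0, duration]", i)
            if abs(ev.t * 1000 - round(ev.t * 1000)) > 1e-6:
                raise EventValidationError("timestamp not a multiple of 1 ms", i)
            if ev.kind == CUE_ON:
                if cue_on:
                    raise EventValidationError("CUE_ON while a cue is already on", i)
                if ev.payload not in ("LARGE", "SMALL"):
                    raise EventValidationError("CUE_ON payload must be LARGE or SMALL", i)
                cue_on = True
            elif ev.kind == CUE_OFF:
                if not cue_on:
                    raise EventValidationError("CUE_OFF without a preceding CUE_ON", i)
                cue_on = False
            elif ev.kind == ENTRY:
                if inside:
                    raise EventValidationError("ENTRY while already inside receptacle", i)
                inside = True
            elif ev.kind == EXIT:
                if not inside:
                    raise EventValidationError("EXIT before any ENTRY", i)
                inside = False
            prev_t = ev.t

    def of_kind(self, kind: str) -> list[Event]:
        return [ev for ev in self.events if ev.kind == kind]


@dataclass(frozen=True)
class TrialRecord:
    """One cue presentation and its outcome.

    ``responded`` (R+) means a receptacle entry occurred during the cue
    window; in that case ``response_entry_time`` holds the entry timestamp and
    the cue offset coincides with it. A non-responded (R-) trial has the cue
    off exactly 5 s after onset. ``iti_preceding`` is measured from the
    previous cue's offset (session start for the first trial).
    """

    index: int
    cue_type: str
    cue_onset: float
    cue_offset: float
    iti_preceding: float
    responded: bool
    response_entry_time: float | None = None


@dataclass
class TrackingTrace:
    """Per-frame positions of the two head LEDs, in pixels.

    ``red`` and ``green`` are (n_frames, 2) float arrays with NaN marking
    frames where that LED was not tracked.
    """

    frame_rate: float
    red: np.ndarray
    green: np.ndarray
    cm_per_pixel: float

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape or self.red.ndim != 2 or self.red.shape[1] != 2:
            raise ValueError("red and green must both be (n_frames, 2) arrays")
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]


# ---------------------------------------------------------------------------
# events.csv
# ---------------------------------------------------------------------------

def write_events(session: SessionEvents, path) -> None:
    """Write ``events.csv`` with integer-millisecond timestamps."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("t_ms,kind,payload\n")
        for ev in session.events:
            payload = "" if ev.payload is None else ev.payload
            fh.write(f"{ev.t_ms},{ev.kind},{payload}\n")


def read_events(path, session_id: str = "", condition_label: str = "",
                duration: float | None = None) -> SessionEvents:
    """Parse ``events.csv``; malformed rows are reported with line numbers.

    ``duration`` defaults to the last timestamp when no sidecar value is
    supplied.
    """
    path = Path(path)
    events: list[Event] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["t_ms", "kind"]:
            raise EventValidationError(f"unexpected header {header!r}", 1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise EventValidationError(f"expected 3 fields, got {len(parts)}", lineno)
            t_ms_s, kind, payload_s = parts
            try:
                t_ms = int(t_ms_s)
            except ValueError:
                raise EventValidationError(f"bad timestamp {t_ms_s!r}", lineno) from None
            if kind not in _KINDS:
                raise EventValidationError(f"unknown event kind {kind!r}", lineno)
            payload: object = None
            if kind == CUE_ON:
                payload = payload_s
            elif kind == REWARD and payload_s:
                payload = float(payload_s)
            events.append(Event(t_ms / 1000.0, kind, payload))
    if duration is None:
        duration = events[-1].t if events else 0.0
    try:
        return SessionEvents(session_id or path.stem, condition_label, duration, events)
    except EventValidationError:
        # Re-run validation with knowledge of source lines for a better message.
        _revalidate_with_lines(events, duration)
        raise


def _revalidate_with_lines(events: Sequence[Event], duration: float) -> None:
    probe = SessionEvents.__new__(SessionEvents)
    probe.session_id = ""
    probe.condition_label = ""
    probe.duration = duration
    for n in range(1, len(events) + 1):
        probe.events = list(events[:n])
        try:
            probe.validate()
        except EventValidationError as exc:
            raise EventValidationError(str(exc).split(": ", 1)[-1], n + 1) from None


# ---------------------------------------------------------------------------
# tracking.csv
# ---------------------------------------------------------------------------

def write_tracking(trace: TrackingTrace, path) -> None:
    def fmt(v: float) -> str:
        return "" if math.isnan(v) else f"{v:.3f}"

    with open(path, "w") as fh:
        fh.write("frame,red_x,red_y,green_x,green_y\n")
        for i in range(trace.n_frames):
            r, g = trace.red[i], trace.green[i]
            fh.write(f"{i},{fmt(r[0])},{fmt(r[1])},{fmt(g[0])},{fmt(g[1])}\n")


def read_tracking(path, frame_rate: float = 30.0, cm_per_pixel: float = 0.1) -> TrackingTrace:
    df = pd.read_csv(path)
    expected = ["frame", "red_x", "red_y", "green_x", "green_y"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected tracking columns {list(df.columns)}")
    red = df[["red_x", "red_y"]].to_numpy(dtype=float)
    green = df[["green_x", "green_y"]].to_numpy(dtype=float)
    # A frame with only one coordinate of an LED is treated as missing that LED.
    red[np.isnan(red).any(axis=1)] = np.nan
    green[np.isnan(green).any(axis=1)] = np.nan
    return TrackingTrace(frame_rate, red, green, cm_per_pixel)


# ---------------------------------------------------------------------------
# session directory (events + tracking + sidecar)
# ---------------------------------------------------------------------------

def write_session(session: SessionEvents, out_dir, trace: TrackingTrace | None = None) -> Path:
    """Write a session directory: events.csv, session.json, optional tracking.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_events(session, out_dir / "events.csv")
    meta = {
        "session_id": session.session_id,
        "condition_label": session.condition_label,
        "duration": session.duration,
    }
    if trace is not None:
        write_tracking(trace, out_dir / "tracking.csv")
        meta["frame_rate"] = trace.frame_rate
        meta["cm_per_pixel"] = trace.cm_per_pixel
    with open(out_dir / "session.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out_dir


def read_session(session_dir) -> tuple[SessionEvents, TrackingTrace | None]:
    session_dir = Path(session_dir)
    with open(session_dir / "session.json") as fh:
        meta = json.load(fh)
    events = read_events(
        session_dir / "events.csv",
        session_id=meta["session_id"],
        condition_label=meta.get("condition_label", ""),
        duration=meta["duration"],
    )
    trace = None
    tpath = session_dir / "tracking.csv"
    if tpath.exists():
        trace = read_tracking(
            tpath,
            frame_rate=meta.get("frame_rate", 30.0),
            cm_per_pixel=meta.get("cm_per_pixel", 0.1),
        )
    return events, trace


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

def build_trial_table(session: SessionEvents) -> list[TrialRecord]:
    """Derive one :class:`TrialRecord` per cue presentation.

    A trial is responded (R+) iff a receptacle ENTRY falls within
    ``[cue_onset, min(cue_onset + 5 s, cue_offset)]``. An animal already
    inside the receptacle at cue onset does not count unless it re-enters
    during the cue. The preceding inter-trial interval runs from the previous
    cue's offset (session start for the first trial).
    """
    entry_times = np.array([ev.t for ev in session.of_kind(ENTRY)])
    trials: list[TrialRecord] = []
    prev_off = 0.0
    pending_on: Event | None = None
    for ev in session.events:
        if ev.kind == CUE_ON:
            pending_on = ev
        elif ev.kind == CUE_OFF:
            if pending_on is None:
                raise EventValidationError("CUE_OFF without matching CUE_ON")
            onset, offset = pending_on.t, ev.t
            window_end = min(onset + CUE_WINDOW, offset)
            in_window = entry_times[(entry_times >= onset) & (entry_times <= window_end)]
            responded = in_window.size > 0
            trials.append(
                TrialRecord(
                    index=len(trials),
                    cue_type=str(pending_on.payload),
                    cue_onset=onset,
                    cue_offset=offset,
                    iti_preceding=onset - prev_off,
                    responded=responded,
                    response_entry_time=float(in_window[0]) if responded else None,
                )
            )
            prev_off = offset
            pending_on = None
    if pending_on is not None:
        raise EventValidationError("CUE_ON without matching CUE_OFF")
    return trials


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a trial table."""
    return pd.DataFrame(
        {
            "index": t.index,
            "cue_type": t.cue_type,
            "cue_onset": t.cue_onset,
            "cue_offset": t.cue_offset,
            "iti_preceding": t.iti_preceding,
            "responded": t.responded,
            "response_entry_time": (
                np.nan if t.response_entry_time is None else t.response_entry_time
            ),
        }
        for t in trials
    )
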