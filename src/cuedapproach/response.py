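"""Response ratios in time bins and pause (non-responsive-cluster) statistics.

The response ratio is the fraction of cues responded to among cues presented
within a time bin (15-min or 1-h bins in the original analyses), expressed as
a percent. A *pause* is a maximal run of at least two consecutive
non-responded (R-) trials; its length is the time between the flanking
responded cues, and the cumulative time in pauses plotted against sequential
pause number characterises how non-responsive episodes lengthen over a
session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .session import TrialRecord

__all__ = [
    "response_ratio",
    "session_response_ratio",
    "detect_pauses",
    "cumulative_pause_curve",
    "PauseRecord",
]


def response_ratio(
    trials: Sequence[TrialRecord],
    bin_width: float,
    cue_filter: str | None = None,
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Tabulate per-bin response ratios, split by cue type.

    Each cue is assigned to the bin containing its onset. Bins with no cues
    carry NaN (an undefined ratio is not evidence of non-responding). The
    returned frame has one row per (bin, cue type) with columns
    ``bin_start, bin_end, cue_type, n_cues, n_responded, ratio_pct``.

    ``span`` bounds the analysed interval (default: 0 to the last bin edge
    covering the final cue); ``cue_filter`` restricts to one cue type.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    recs = [t for t in trials if cue_filter is None or t.cue_type == cue_filter]
    if span is None:
        t_end = max((t.cue_onset for t in recs), default=0.0)
        span = (0.0, (np.floor(t_end / bin_width) + 1) * bin_width if recs else bin_width)
    lo, hi = span
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    if edges[-1] < hi - 1e-9:
        edges = np.append(edges, hi)
    cue_types = sorted({t.cue_type for t in recs}) or ["LARGE", "SMALL"]
    rows = []
    for ct in cue_types:
        onsets = np.array([t.cue_onset for t in recs if t.cue_type == ct])
        hits = np.array([t.responded for t in recs if t.cue_type == ct], dtype=bool)
        for b in range(len(edges) - 1):
            in_bin = (onsets >= edges[b]) & (onsets < edges[b + 1])
            n = int(in_bin.sum())
            k = int(hits[in_bin].sum())
            rows.append(
                dict(
                    bin_start=edges[b],
                    bin_end=edges[b + 1],
                    cue_type=ct,
                    n_cues=n,
                    n_responded=k,
                    ratio_pct=100.0 * k / n if n else np.nan,
                )
            )
    return pd.DataFrame(rows)


def session_response_ratio(
    trials: Sequence[TrialRecord],
    window: tuple[float, float] | None = None,
    cue_filter: str | None = None,
) -> float:
    """Single response ratio (percent) over a time window; NaN if no cues."""
    sel = [
        t
        for t in trials
        if (cue_filter is None or t.cue_type == cue_filter)
        and (window is None or window[0] <= t.cue_onset < window[1])
    ]
    if not sel:
        return float("nan")
    return 100.0 * sum(t.responded for t in sel) / len(sel)


@dataclass(frozen=True)
class PauseRecord:
    """A maximal run of >= 2 consecutive R- trials.

    ``duration`` is measured between the cue onsets of the flanking responded
    cues; when no responded cue bounds the run, the session start or end
    stands in and the corresponding censoring flag is set.
    """

    start_trial: int
    n_missed: int
    duration: float
    left_censored: bool = False
    right_censored: bool = False


def detect_pauses(
    trials: Sequence[TrialRecord],
    session_duration: float | None = None,
) -> list[PauseRecord]:
    """Find all pauses (runs of >= 2 consecutive non-responses).

    Isolated single R- trials yield no record. ``session_duration`` supplies
    the right boundary for a run that extends to the final trial (defaults to
    the last cue offset).
    """
    trials = list(trials)
    if not trials:
        return []
    if session_duration is None:
        session_duration = trials[-1].cue_offset
    flags = [t.responded for t in trials]
    pauses: list[PauseRecord] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            i += 1
            continue
        j = i
        while j < n and not flags[j]:
            j += 1
        run = j - i
        if run >= 2:
            left_censored = i == 0
            right_censored = j == n
            t0 = 0.0 if left_censored else trials[i - 1].cue_onset
            t1 = session_duration if right_censored else trials[j].cue_onset
            pauses.append(
                PauseRecord(
                    start_trial=i,
                    n_missed=run,
                    duration=t1 - t0,
                    left_censored=left_censored,
                    right_censored=right_censored,
                )
            )
        i = j
    return pauses


def cumulative_pause_curve(pauses: Sequence[PauseRecord]) -> pd.DataFrame:
    """Cumulative seconds in pauses against sequential pause number.

    Monotone non-decreasing; the final value is the session's total pause
    time. Censored pauses are included.
    """
    durations = np.array([p.duration for p in pauses], dtype=float)
    return pd.DataFrame(
        {
            "pause_number": np.arange(1, len(durations) + 1),
            "cumulative_s": np.cumsum(durations),
        }
    )
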