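"""Video-tracking pipeline: centroid extraction, movement segmentation, and
trial-locked locomotion metrics.

The rat's position is the centroid of two head-mounted LEDs tracked at 30
frames/s. Missing-frame gaps of up to 10 frames are linearly interpolated;
longer gaps are discarded (frames marked invalid). Movement is detected from
the log-transformed rolling SD of centroid dispersion in a 200-ms window:
its distribution is bimodal (stillness vs. locomotion), a two-Gaussian
mixture is fitted, the movement threshold is placed where the two weighted
component densities intersect, and a movement bout is >= 8 consecutive
supra-threshold frames.

Trial-locked metrics: latency to initiate movement and to reach the
receptacle after cue onset, path length and path efficiency (straight-line
distance from the cue-onset position to the receptacle divided by the path
actually taken, in (0, 1]), distance travelled during inter-trial intervals,
receptacle entry rates in the 5 s before versus during the cue, and the
response ratio as a function of preceding-ITI length in 10-s bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.mixture import GaussianMixture

from .session import ENTRY, SessionEvents, TrackingTrace, TrialRecord

__all__ = [
    "CentroidTrace",
    "MovementSegmentation",
    "UnimodalDataError",
    "compute_centroid",
    "rolling_log_sd",
    "weighted_gaussian_intersection",
    "fit_movement_threshold",
    "segment_movement",
    "segment_session",
    "approach_metrics",
    "iti_locomotion",
    "receptacle_entry_rate",
    "response_by_iti_bin",
]

LOG_SD_EPS = 1e-6  # cm, inside the log transform
MAX_INTERP_GAP = 10  # frames
MIN_BOUT_FRAMES = 8
CUE_WINDOW = 5.0


class UnimodalDataError(ValueError):
    """The log-SD distribution does not separate into two modes."""


@dataclass
class CentroidTrace:
    """Per-frame centroid in cm with a validity mask.

    Invalid frames are those inside missing-LED gaps longer than
    :data:`MAX_INTERP_GAP` frames, or gaps bordering the trace ends.
    """

    frame_rate: float
    xy: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def frame_of(self, t: float) -> int:
        return int(np.clip(round(t * self.frame_rate), 0, self.n_frames - 1))


@dataclass
class MovementSegmentation:
    """Movement-threshold fit and the resulting bouts.

    Component 1 is the low (stillness) mode, component 2 the movement mode;
    ``threshold`` lies between their means at the weighted-density
    intersection. ``bouts`` are half-open frame ranges [start, end).
    """

    log_sd: np.ndarray
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    bouts: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------

def _nan_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    runs = []
    n = missing.size
    i = 0
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def compute_centroid(trace: TrackingTrace) -> CentroidTrace:
    """Midpoint of the two LEDs, gap-filled and scaled to cm.

    A frame's centroid exists only when both LEDs are tracked. Missing runs
    of up to 10 frames are linearly interpolated between the flanking valid
    centroids; longer runs, and runs touching the trace ends, are marked
    invalid.
    """
    both = ~(np.isnan(trace.red).any(axis=1) | np.isnan(trace.green).any(axis=1))
    if both.sum() < 2:
        raise ValueError("need at least 2 frames with both LEDs tracked")
    xy = 0.5 * (trace.red + trace.green) * trace.cm_per_pixel
    valid = both.copy()
    for i0, i1 in _nan_runs(~both):
        gap = i1 - i0
        if gap <= MAX_INTERP_GAP and i0 > 0 and i1 < trace.n_frames:
            a, b = xy[i0 - 1], xy[i1]
            frac = (np.arange(1, gap + 1) / (gap + 1))[:, None]
            xy[i0:i1] = a + frac * (b - a)
            valid[i0:i1] = True
        else:
            xy[i0:i1] = np.nan
    return CentroidTrace(frame_rate=trace.frame_rate, xy=xy, valid=valid)


# ---------------------------------------------------------------------------
# rolling log-SD
# ---------------------------------------------------------------------------

def rolling_log_sd(
    ct: CentroidTrace,
    window: float = 0.2,
    method: str = "meandist",
) -> np.ndarray:
    """Log-transformed SD of centroid dispersion in a centered window.

    The window spans ``round(window * frame_rate)`` frames, widened to the
    next odd count so it centers on each frame (7 frames ~= 233 ms at 30
    fps). Per frame, over the windowed centroids:

    - ``"meandist"`` (default): SD of each centroid's Euclidean distance
      from the window's mean centroid;
    - ``"step"``: SD of successive frame-to-frame displacement magnitudes;
    - ``"pairwise"``: SD of all pairwise inter-centroid distances.

    The natural log of (SD + 1e-6 cm) is returned; frames whose window
    contains any invalid frame, or that sit within half a window of the
    trace ends, are NaN.
    """
    w = int(round(window * ct.frame_rate))
    if w < 2:
        raise ValueError("window must cover at least 2 frames")
    if w % 2 == 0:
        w += 1
    half = w // 2
    n = ct.n_frames
    out = np.full(n, np.nan)
    if n < w:
        return out
    wins = sliding_window_view(ct.xy, w, axis=0)          # (n-w+1, 2, w)
    ok = sliding_window_view(ct.valid, w).all(axis=1)     # (n-w+1,)
    if method == "meandist":
        mean = wins.mean(axis=2, keepdims=True)
        d = np.linalg.norm(wins - mean, axis=1)           # (n-w+1, w)
        sd = d.std(axis=1)
    elif method == "step":
        steps = np.linalg.norm(np.diff(wins, axis=2), axis=1)
        sd = steps.std(axis=1)
    elif method == "pairwise":
        iu, ju = np.triu_indices(w, k=1)
        diffs = wins[:, :, iu] - wins[:, :, ju]
        sd = np.linalg.norm(diffs, axis=1).std(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    centre = np.arange(half, n - half)
    out[centre] = np.where(ok, np.log(sd + LOG_SD_EPS), np.nan)
    return out


# ---------------------------------------------------------------------------
# movement threshold
# ---------------------------------------------------------------------------

def weighted_gaussian_intersection(
    m1: float, s1: float, w1: float, m2: float, s2: float, w2: float
) -> float:
    """Abscissa in (m1, m2) where two weighted normal densities are equal.

    Solves w1 N(x; m1, s1) = w2 N(x; m2, s2) (a quadratic in x) and returns
    the root strictly between the means — the point of least overlap between
    the lower and upper distributions. Requires m1 < m2.
    """
    if not m1 < m2:
        raise ValueError("need m1 < m2")
    k = np.log((w1 * s2) / (w2 * s1))
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + k
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            raise UnimodalDataError("densities never cross between the means")
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise UnimodalDataError("densities never cross between the means")
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise UnimodalDataError("no density intersection between the component means")
    return float(inside[0])


def fit_movement_threshold(log_sd: np.ndarray) -> MovementSegmentation:
    """Fit a two-Gaussian mixture to valid log-SD values and set the threshold.

    EM runs on the raw values with deterministic initialisation (component
    means at the 25th/75th percentiles, equal weights, pooled variance), so
    the fit needs no random seed. The movement threshold is the weighted
    component-density intersection between the two means. A collapsed fit
    (component weight < 0.01, SD < 1e-6, or unseparated means) raises
    :class:`UnimodalDataError`.
    """
    x = np.asarray(log_sd, dtype=float)
    vals = x[np.isfinite(x)]
    if vals.size < 200:
        raise ValueError(f"need >= 200 valid log-SD values, got {vals.size}")
    if vals.std() == 0.0:
        raise UnimodalDataError("log-SD values are constant")
    q25, q75 = np.percentile(vals, [25, 75])
    var = vals.var()
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        weights_init=[0.5, 0.5],
        means_init=[[q25], [q75]],
        precisions_init=[[[1.0 / var]], [[1.0 / var]]],
        max_iter=500,
        tol=1e-7,
        reg_covar=1e-12,
        n_init=1,
        random_state=0,
    ).fit(vals.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    if weights.min() < 0.01 or sds.min() < 1e-6:
        raise UnimodalDataError("mixture collapsed: data look unimodal")
    if means[1] - means[0] < 1e-3:
        raise UnimodalDataError("component means are not separated")
    threshold = weighted_gaussian_intersection(
        means[0], sds[0], weights[0], means[1], sds[1], weights[1]
    )

    # the least-overlap point is only meaningful when the fitted mixture is
    # genuinely bimodal: the density at the crossing must sit in a valley
    def mixture_pdf(x: float) -> float:
        return sum(
            wt * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
            for mu, sd, wt in zip(means, sds, weights)
        )

    if mixture_pdf(threshold) >= min(mixture_pdf(means[0]), mixture_pdf(means[1])):
        raise UnimodalDataError(
            "no density valley between the component means: data look unimodal"
        )
    return MovementSegmentation(
        log_sd=x,
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        threshold=threshold,
    )


def segment_movement(
    log_sd: np.ndarray,
    threshold: float,
    min_frames: int = MIN_BOUT_FRAMES,
) -> list[tuple[int, int]]:
    """Maximal runs of >= ``min_frames`` consecutive supra-threshold frames.

    Returns half-open frame ranges [start, end). NaN (invalid) frames break
    runs; runs shorter than ``min_frames`` yield no bout.
    """
    supra = np.isfinite(log_sd) & (log_sd > threshold)
    return [(i0, i1) for i0, i1 in _nan_runs(supra) if i1 - i0 >= min_frames]


def segment_session(
    ct: CentroidTrace,
    window: float = 0.2,
    method: str = "meandist",
) -> MovementSegmentation:
    """Full movement segmentation of one session's centroid trace."""
    log_sd = rolling_log_sd(ct, window=window, method=method)
    seg = fit_movement_threshold(log_sd)
    seg.bouts = segment_movement(log_sd, seg.threshold)
    return seg


# ---------------------------------------------------------------------------
# trial-locked metrics
# ---------------------------------------------------------------------------

def approach_metrics(
    trials: Sequence[TrialRecord],
    ct: CentroidTrace,
    seg: MovementSegmentation,
    receptacle: tuple[float, float],
) -> pd.DataFrame:
    """Per responded trial: approach latencies, path length and efficiency.

    ``movement_onset_latency`` is the start of the first movement bout in
    [cue onset, entry]; if a bout already spans cue onset it is 0 and the
    trial is flagged ``moving_at_cue``; NaN if no bout registered.
    ``path_length`` sums successive centroid displacements from the
    cue-onset position to the entry; ``path_efficiency`` is the straight
    line to the receptacle over that path, clipped to <= 1. Trials whose
    window touches invalid tracking are excluded with a reason.
    """
    receptacle = np.asarray(receptacle, dtype=float)
    rows = []
    for t in trials:
        if not t.responded or t.response_entry_time is None:
            continue
        f_on = ct.frame_of(t.cue_onset)
        f_in = ct.frame_of(t.response_entry_time)
        row = dict(
            trial=t.index,
            cue_onset=t.cue_onset,
            receptacle_latency=t.response_entry_time - t.cue_onset,
            movement_onset_latency=np.nan,
            path_length=np.nan,
            path_efficiency=np.nan,
            moving_at_cue=False,
            excluded=False,
            exclude_reason="",
        )
        if not ct.valid[f_on : f_in + 1].all():
            row["excluded"] = True
            row["exclude_reason"] = "invalid tracking in trial window"
            rows.append(row)
            continue
        steps = np.linalg.norm(np.diff(ct.xy[f_on : f_in + 1], axis=0), axis=1)
        path = float(steps.sum())
        straight = float(np.linalg.norm(ct.xy[f_on] - receptacle))
        row["path_length"] = path
        row["path_efficiency"] = 1.0 if path <= straight or path == 0.0 else straight / path
        for b0, b1 in seg.bouts:
            if b0 < f_on < b1:
                row["movement_onset_latency"] = 0.0
                row["moving_at_cue"] = True
                break
            if f_on <= b0 <= f_in:
                row["movement_onset_latency"] = b0 / ct.frame_rate - t.cue_onset
                break
            if b0 > f_in:
                break
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "trial", "cue_onset", "receptacle_latency", "movement_onset_latency",
            "path_length", "path_efficiency", "moving_at_cue", "excluded",
            "exclude_reason",
        ],
    )


def iti_locomotion(trials: Sequence[TrialRecord], ct: CentroidTrace) -> pd.DataFrame:
    """Distance travelled during each trial's preceding inter-trial interval.

    The window runs from the previous cue's offset to this cue's onset
    (session start for the first trial). ``next_trial_responded`` carries the
    upcoming trial's R+/R- flag so locomotion can be split by whether the ITI
    preceded a cued approach. ITIs touching invalid tracking are excluded.
    """
    rows = []
    for t in trials:
        t0 = t.cue_onset - t.iti_preceding
        f0, f1 = ct.frame_of(t0), ct.frame_of(t.cue_onset)
        excluded = not ct.valid[f0 : f1 + 1].all()
        if excluded or f1 <= f0:
            dist = np.nan
        else:
            dist = float(
                np.linalg.norm(np.diff(ct.xy[f0 : f1 + 1], axis=0), axis=1).sum()
            )
        rows.append(
            dict(
                trial=t.index,
                iti_duration=t.iti_preceding,
                iti_distance=dist,
                iti_rate=dist / t.iti_preceding if t.iti_preceding > 0 else np.nan,
                next_trial_responded=t.responded,
                excluded=excluded,
            )
        )
    return pd.DataFrame(rows)


def receptacle_entry_rate(
    trials: Sequence[TrialRecord],
    events: SessionEvents,
) -> tuple[float, float]:
    """Entry rates (Hz) in the 5 s before versus the 5 s from cue onset,
    pooled over rewarded trials.

    Counts are summed over all rewarded (responded) trials and divided by
    (number of rewarded trials x 5 s), the longest possible trial length.
    Windows are half-open, so an entry exactly at cue onset counts as
    post-cue. Returns (nan, nan) when no trial was rewarded.
    """
    entry_times = np.array([ev.t for ev in events.of_kind(ENTRY)])
    rewarded = [t for t in trials if t.responded]
    if not rewarded:
        return (float("nan"), float("nan"))
    pre = post = 0
    for t in rewarded:
        pre += int(((entry_times >= t.cue_onset - CUE_WINDOW) & (entry_times < t.cue_onset)).sum())
        post += int(((entry_times >= t.cue_onset) & (entry_times < t.cue_onset + CUE_WINDOW)).sum())
    denom = len(rewarded) * CUE_WINDOW
    return (pre / denom, post / denom)


def response_by_iti_bin(
    trials: Sequence[TrialRecord],
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Response ratio as a function of preceding-ITI length, in 10-s bins.

    Trials are bucketed by ``iti_preceding`` into [0, 10), [10, 20), ...;
    empty bins carry NaN ratios.
    """
    trials = list(trials)
    if not trials:
        return pd.DataFrame(
            columns=["bin_start", "bin_end", "n_trials", "n_responded", "ratio_pct"]
        )
    itis = np.array([t.iti_preceding for t in trials])
    flags = np.array([t.responded for t in trials], dtype=bool)
    n_bins = int(np.floor(itis.max() / bin_width)) + 1
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        in_bin = (itis >= lo) & (itis < hi)
        n = int(in_bin.sum())
        k = int(flags[in_bin].sum())
        rows.append(
            dict(
                bin_start=lo,
                bin_end=hi,
                n_trials=n,
                n_responded=k,
                ratio_pct=100.0 * k / n if n else np.nan,
            )
        )
    return pd.DataFrame(rows)
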