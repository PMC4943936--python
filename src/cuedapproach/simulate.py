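"""Synthetic cued-approach sessions: event logs and video-tracking traces.

The generator realises the task contingencies of a two-cue sucrose-seeking
session: cue onsets separated by truncated-exponential inter-trial intervals
(realized mean 30 s), a latent two-state (responsive / non-responsive) Markov
process over trials whose transition matrix can change at hour boundaries,
state- and cue-conditional Bernoulli response emissions, in-window receptacle
entries that terminate the cue and trigger reward, spontaneous uncued entries,
and a 30 frames/s two-LED trajectory with locomotor bouts, cued approach
paths, positional jitter and missing frames.

Every stage is driven by a single :class:`numpy.random.Generator`, so a given
(config, seed) pair reproduces a session bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import GeneratorConfig, InvalidConfigError
from .session import CUE_OFF, CUE_ON, ENTRY, EXIT, REWARD, Event, SessionEvents, TrackingTrace

__all__ = [
    "truncated_exponential_rate",
    "truncated_exponential_cdf",
    "sample_iti",
    "sample_markov_chain",
    "stationary_occupancy",
    "generate_trial_sequence",
    "generate_session_events",
    "generate_tracking_trace",
    "SimulatedSession",
    "simulate_session",
    "simulate_cohort",
]

RESPONSIVE, NONRESPONSIVE = 0, 1


# ---------------------------------------------------------------------------
# inter-trial intervals
# ---------------------------------------------------------------------------

def _trunc_exp_mean(rate: float, lo: float, hi: float) -> float:
    d = stats.truncexpon(b=(hi - lo) * rate, loc=lo, scale=1.0 / rate)
    return float(d.mean())


def truncated_exponential_rate(mean: float, lo: float, hi: float) -> float:
    """Rate of the parent exponential whose [lo, hi]-truncation has ``mean``.

    The achievable range of the truncated mean is (lo, (lo + hi)/2): the
    truncated distribution tends to a point mass at ``lo`` as the rate grows
    and to uniform on [lo, hi] as it vanishes. Raises
    :class:`~cuedapproach.config.InvalidConfigError` outside that range.
    """
    if hi <= lo:
        raise InvalidConfigError("need lo < hi to calibrate the ITI rate")
    midpoint = (lo + hi) / 2.0
    if not lo < mean < midpoint:
        raise InvalidConfigError(
            f"truncated mean {mean} unachievable on [{lo}, {hi}]; "
            f"must lie strictly between {lo} and {midpoint}"
        )
    return float(optimize.brentq(
        lambda lam: _trunc_exp_mean(lam, lo, hi) - mean, 1e-9, 1e3, xtol=1e-12
    ))


def truncated_exponential_cdf(x, mean: float, lo: float, hi: float) -> np.ndarray:
    """CDF of the calibrated truncated exponential (analytic reference)."""
    lam = truncated_exponential_rate(mean, lo, hi)
    x = np.asarray(x, dtype=float)
    num = 1.0 - np.exp(-lam * (np.clip(x, lo, hi) - lo))
    den = 1.0 - math.exp(-lam * (hi - lo))
    return np.where(x < lo, 0.0, np.where(x > hi, 1.0, num / den))


def sample_iti(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` inter-trial intervals (seconds).

    The parent exponential's rate is solved so the *realized* mean of the
    truncated distribution equals ``config.iti_mean``. Degenerate bounds
    (lo == hi) yield that constant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = config.iti_bounds
    if hi == lo:
        if abs(config.iti_mean - lo) > 1e-9:
            raise InvalidConfigError("degenerate iti_bounds require iti_mean == bound")
        return np.full(n, float(lo))
    lam = truncated_exponential_rate(config.iti_mean, lo, hi)
    d = stats.truncexpon(b=(hi - lo) * lam, loc=lo, scale=1.0 / lam)
    return np.asarray(d.rvs(size=n, random_state=rng), dtype=float)


# ---------------------------------------------------------------------------
# latent state chain
# ---------------------------------------------------------------------------

def stationary_occupancy(matrix: np.ndarray) -> float:
    """P(responsive) under the stationary law of a 2x2 transition matrix.

    Both off-diagonals zero (two absorbing states) has no unique stationary
    law; 0.5 is returned as the symmetric convention.
    """
    p = float(matrix[RESPONSIVE, NONRESPONSIVE])
    q = float(matrix[NONRESPONSIVE, RESPONSIVE])
    if p + q == 0.0:
        return 0.5
    return q / (p + q)


def sample_markov_chain(
    matrix: np.ndarray,
    n: int,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> np.ndarray:
    """Simulate ``n`` steps of a fixed 2-state chain (0 = responsive)."""
    matrix = np.asarray(matrix, dtype=float)
    states = np.empty(n, dtype=np.int64)
    if initial_state is None:
        states[0] = RESPONSIVE if rng.random() < stationary_occupancy(matrix) else NONRESPONSIVE
    else:
        states[0] = initial_state
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for k in range(1, n):
        stay = matrix[states[k - 1], states[k - 1]]
        states[k] = states[k - 1] if u[k - 1] < stay else 1 - states[k - 1]
    return states


def generate_trial_sequence(
    config: GeneratorConfig,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Roll out the latent state and per-trial skeleton for one session.

    The chain switches transition matrices at hour boundaries; the matrix in
    force for the step from trial *k* to *k+1* is the one covering trial
    *k*'s cue onset (the antecedent of the couplet). The initial state is
    drawn from the first hour's stationary law unless given. Each trial's
    responded flag is Bernoulli in the state- and cue-conditional emission
    probability; responded trials carry an in-window entry latency, so the
    cue span is that latency for R+ trials and the full window for R-.

    Returns the latent state array and a skeleton table with columns
    ``cue_onset, cue_offset, cue_type, iti_preceding, state, responded,
    entry_latency``. The sequence stops when the next cue window would
    overrun the session.
    """
    lm = config.latency_model
    entry_dist = stats.truncnorm(
        (lm.entry_min - lm.entry_mean) / lm.entry_sd,
        (lm.entry_max - lm.entry_mean) / lm.entry_sd,
        loc=lm.entry_mean,
        scale=lm.entry_sd,
    )
    lo, hi = config.iti_bounds
    if hi > lo:
        lam = truncated_exponential_rate(config.iti_mean, lo, hi)
        span_mass = 1.0 - math.exp(-lam * (hi - lo))

        def draw_iti() -> float:
            return lo - math.log1p(-rng.random() * span_mass) / lam

    else:

        def draw_iti() -> float:
            return lo

    if initial_state is None:
        pi0 = stationary_occupancy(config.matrix_for_hour(0))
        state = RESPONSIVE if rng.random() < pi0 else NONRESPONSIVE
    else:
        state = int(initial_state)

    rows = []
    t = 0.0
    prev_offset = 0.0
    while True:
        iti = draw_iti()
        onset = prev_offset + iti
        if onset + config.cue_duration_max > config.session_duration:
            break
        if rows:
            hour = int(rows[-1]["cue_onset"] // 3600.0)
            m = config.matrix_for_hour(hour)
            stay = m[state, state]
            if rng.random() >= stay:
                state = 1 - state
        cue_type = "LARGE" if rng.random() < config.cue_mix else "SMALL"
        p_r, p_n = config.p_respond_given_state[cue_type]
        p = p_r if state == RESPONSIVE else p_n
        responded = bool(rng.random() < p)
        entry_latency = float(entry_dist.rvs(random_state=rng)) if responded else np.nan
        offset = onset + (entry_latency if responded else config.cue_duration_max)
        rows.append(
            dict(
                cue_onset=onset,
                cue_offset=offset,
                cue_type=cue_type,
                iti_preceding=iti,
                state=state,
                responded=responded,
                entry_latency=entry_latency,
            )
        )
        prev_offset = offset
    skeleton = pd.DataFrame(
        rows,
        columns=[
            "cue_onset", "cue_offset", "cue_type", "iti_preceding",
            "state", "responded", "entry_latency",
        ],
    )
    return skeleton["state"].to_numpy(dtype=np.int64, copy=True) if rows else np.empty(0, np.int64), skeleton


# ---------------------------------------------------------------------------
# event stream
# ---------------------------------------------------------------------------

def _round_ms(t: float) -> float:
    return round(t * 1000.0) / 1000.0


def generate_session_events(
    config: GeneratorConfig,
    rng: np.random.Generator,
    session_id: str = "sim",
    skeleton: pd.DataFrame | None = None,
) -> tuple[SessionEvents, pd.DataFrame]:
    """Realise a trial skeleton as a millisecond-stamped event stream.

    For R+ trials the receptacle ENTRY lands at cue onset plus the sampled
    in-window latency; the cue terminates at that instant and REWARD follows
    immediately (reward is contingent on entry during the cue). The animal
    exits after a consumption period. R- trials carry CUE_OFF at onset + 5 s
    and no in-window entry. Spontaneous entries during ITIs form a Poisson
    process at ``config.spontaneous_entry_rate`` and never intrude into cue
    windows. All timestamps round to 1 ms.

    Returns the event stream and the trial table augmented with realised
    ``entry_time`` and ``exit_time`` columns (NaN for R- trials).
    """
    if skeleton is None:
        _, skeleton = generate_trial_sequence(config, rng)
    trials = skeleton.copy()
    lm = config.latency_model
    vol_large, vol_small = config.reward_volumes
    consume = stats.truncnorm(
        (0.5 - lm.consume_mean) / lm.consume_sd,
        (8.0 - lm.consume_mean) / lm.consume_sd,
        loc=lm.consume_mean,
        scale=lm.consume_sd,
    )

    events: list[Event] = []
    entry_times = np.full(len(trials), np.nan)
    exit_times = np.full(len(trials), np.nan)
    free_from = 0.0  # receptacle is unoccupied and no cue on from this time
    onsets = trials["cue_onset"].to_numpy() if len(trials) else np.empty(0)
    for k, row in enumerate(trials.itertuples(index=False)):
        onset = row.cue_onset
        # spontaneous entries in the open ITI window before this cue
        window_lo, window_hi = free_from + 0.05, onset - 0.05
        if window_hi > window_lo and config.spontaneous_entry_rate > 0:
            n_spont = rng.poisson(config.spontaneous_entry_rate * (window_hi - window_lo))
            times = np.sort(rng.uniform(window_lo, window_hi, size=n_spont))
            cursor = window_lo
            for te in times:
                if te <= cursor:
                    continue
                dwell = float(rng.uniform(0.3, 1.2))
                tx = min(te + dwell, window_hi)
                if tx <= te:
                    continue
                events.append(Event(_round_ms(te), ENTRY))
                events.append(Event(_round_ms(tx), EXIT))
                cursor = tx + 0.05
        events.append(Event(_round_ms(onset), CUE_ON, row.cue_type))
        if row.responded:
            t_entry = onset + row.entry_latency
            events.append(Event(_round_ms(t_entry), ENTRY))
            events.append(Event(_round_ms(t_entry), CUE_OFF))
            vol = vol_large if row.cue_type == "LARGE" else vol_small
            events.append(Event(_round_ms(t_entry), REWARD, vol))
            next_onset = onsets[k + 1] if k + 1 < len(onsets) else config.session_duration
            t_exit = min(t_entry + float(consume.rvs(random_state=rng)),
                         next_onset - 0.1, config.session_duration)
            t_exit = max(t_exit, t_entry + 0.05)
            events.append(Event(_round_ms(t_exit), EXIT))
            entry_times[k] = _round_ms(t_entry)
            exit_times[k] = _round_ms(t_exit)
            free_from = t_exit
        else:
            t_off = onset + config.cue_duration_max
            events.append(Event(_round_ms(t_off), CUE_OFF))
            free_from = t_off
    trials["entry_time"] = entry_times
    trials["exit_time"] = exit_times
    session = SessionEvents(
        session_id=session_id,
        condition_label=config.condition_label,
        duration=config.session_duration,
        events=events,
    )
    return session, trials


# ---------------------------------------------------------------------------
# tracking trace
# ---------------------------------------------------------------------------

def _bout_target(
    pos: np.ndarray,
    step: float,
    rng: np.random.Generator,
    dims: tuple[float, float],
    margin: float = 1.0,
) -> np.ndarray:
    """Displace ``pos`` by ``step`` cm in a random direction, preferring
    directions that keep the straight path inside the chamber so the realized
    bout length equals speed x duration; folds at the walls as a last resort."""
    target = pos
    for _ in range(8):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        target = pos + step * np.array([np.cos(theta), np.sin(theta)])
        if (
            margin <= target[0] <= dims[0] - margin
            and margin <= target[1] <= dims[1] - margin
        ):
            return target
    return _reflect(target, dims, margin)


def _reflect(point: np.ndarray, dims: tuple[float, float], margin: float = 1.0) -> np.ndarray:
    """Fold a point back into the chamber (mirror at the walls)."""
    out = point.copy()
    for ax, size in enumerate(dims):
        lo, hi = margin, size - margin
        span = hi - lo
        if span <= 0:
            out[ax] = size / 2.0
            continue
        v = (out[ax] - lo) % (2 * span)
        out[ax] = lo + (v if v <= span else 2 * span - v)
    return out


def generate_tracking_trace(
    config: GeneratorConfig,
    trials: pd.DataFrame,
    rng: np.random.Generator,
) -> TrackingTrace:
    """Synthesise the two-LED video trace consistent with a trial table.

    The centroid follows a piecewise-linear path: stationary (jitter only)
    between movements, spontaneous bouts at ``bout_speed`` during ITIs at a
    state-dependent Poisson rate, and for each responded trial a straight
    approach from the position at movement onset to the receptacle, arriving
    at the logged entry time and holding there until the exit. The two LEDs
    sit at a fixed separation about the centroid with independent per-frame
    jitter; frames go missing in short (<= 10) and long (> 10 frame) runs.
    Positions stay inside the chamber.

    ``trials`` must carry ``cue_onset``, ``responded``, ``state``,
    ``entry_time`` and ``exit_time`` (the table returned by
    :func:`generate_session_events`).
    """
    loco = config.locomotion_params
    lm = config.latency_model
    dims = config.chamber_dims
    receptacle = np.asarray(config.receptacle_position, dtype=float)
    n_frames = int(round(config.session_duration * config.frame_rate))

    anchor_t: list[float] = [0.0]
    anchor_xy: list[np.ndarray] = [np.array([dims[0] / 2.0, dims[1] / 2.0])]
    pos = anchor_xy[0].copy()
    t_free = 0.0  # trajectory is undirected from here on

    def add_anchor(t: float, xy: np.ndarray) -> None:
        if t <= anchor_t[-1]:
            t = anchor_t[-1] + 1e-6
        anchor_t.append(float(t))
        anchor_xy.append(np.asarray(xy, dtype=float))

    move_dist = stats.truncnorm(
        (lm.move_min - lm.move_mean) / lm.move_sd, np.inf,
        loc=lm.move_mean, scale=lm.move_sd,
    )

    onsets = trials["cue_onset"].to_numpy() if len(trials) else np.empty(0)
    for k, row in enumerate(trials.itertuples(index=False)):
        onset = row.cue_onset
        # spontaneous bouts in [t_free, onset), rate set by the upcoming
        # trial's latent state (responsive animals roam more between cues)
        rate = (
            loco.bout_rate_responsive
            if row.state == RESPONSIVE
            else loco.bout_rate_nonresponsive
        )
        window = onset - t_free
        if window > 1.0 and rate > 0:
            n_bouts = rng.poisson(rate * window)
            starts = np.sort(rng.uniform(t_free, onset - 0.5, size=n_bouts))
            cursor = t_free
            for ts in starts:
                if ts < cursor:
                    continue
                dur = float(np.clip(rng.exponential(loco.bout_duration_mean), 0.3, 2.0))
                dur = min(dur, onset - 0.2 - ts)
                if dur < 0.3:
                    continue
                target = _bout_target(pos, loco.bout_speed * dur, rng, dims)
                add_anchor(ts, pos)
                add_anchor(ts + dur, target)
                pos = target
                cursor = ts + dur + 0.2
        if row.responded and np.isfinite(row.entry_time):
            latency = row.entry_time - onset
            move_onset = onset + min(float(move_dist.rvs(random_state=rng)), 0.6 * latency)
            add_anchor(move_onset, pos)
            add_anchor(row.entry_time, receptacle)
            pos = receptacle.copy()
            t_exit = row.exit_time if np.isfinite(row.exit_time) else row.entry_time + 1.0
            add_anchor(t_exit, receptacle)
            # departure: step away from the receptacle after reward consumption,
            # kept clear of the next trial's approach window
            dep_t = t_exit + 1.0
            if k + 1 < len(onsets):
                dep_t = min(dep_t, onsets[k + 1] - 0.05)
            if dep_t - t_exit >= 0.2:
                theta = rng.uniform(0.25 * np.pi, 0.75 * np.pi)
                dep = _reflect(
                    receptacle + 8.0 * np.array([np.cos(theta), np.sin(theta)]), dims
                )
                add_anchor(dep_t, dep)
                pos = dep
            else:
                pos = receptacle.copy()
            t_free = dep_t + 0.2
        else:
            t_free = row.cue_offset if np.isfinite(row.cue_offset) else onset

    ft = np.arange(n_frames) / config.frame_rate
    at = np.asarray(anchor_t)
    axy = np.vstack(anchor_xy)
    cx = np.interp(ft, at, axy[:, 0])
    cy = np.interp(ft, at, axy[:, 1])
    centroid = np.column_stack([cx, cy])

    half = np.array([loco.led_separation / 2.0, 0.0])
    red = centroid + half + rng.normal(0.0, loco.jitter_sd, size=(n_frames, 2))
    green = centroid - half + rng.normal(0.0, loco.jitter_sd, size=(n_frames, 2))
    for arr in (red, green):
        arr[:, 0] = np.clip(arr[:, 0], 0.0, dims[0])
        arr[:, 1] = np.clip(arr[:, 1], 0.0, dims[1])

    # missing-frame gaps: both LEDs drop out together
    if loco.gap_rate > 0:
        i = 0
        while i < n_frames:
            if rng.random() < loco.gap_rate:
                if rng.random() < loco.long_gap_fraction:
                    length = 11 + int(rng.integers(0, 15))
                else:
                    length = 1 + int(rng.integers(0, 10))
                red[i:i + length] = np.nan
                green[i:i + length] = np.nan
                i += length + 1
            else:
                i += 1

    return TrackingTrace(
        frame_rate=config.frame_rate,
        red=red / config.cm_per_pixel,
        green=green / config.cm_per_pixel,
        cm_per_pixel=config.cm_per_pixel,
    )


# ---------------------------------------------------------------------------
# whole sessions and cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSession:
    """One generated session: the event stream, the generator's own trial
    table (including the latent state), and optionally the tracking trace."""

    events: SessionEvents
    trials: pd.DataFrame
    trace: TrackingTrace | None = None

    @property
    def session_id(self) -> str:
        return self.events.session_id


def simulate_session(
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence,
    session_id: str | None = None,
    tracking: bool = True,
) -> SimulatedSession:
    """Generate a full session deterministically from (config, seed)."""
    rng = np.random.default_rng(seed)
    if session_id is None:
        label = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
        session_id = f"{config.condition_label}-{label}"
    events, trials = generate_session_events(config, rng, session_id=session_id)
    trace = generate_tracking_trace(config, trials, rng) if tracking else None
    return SimulatedSession(events=events, trials=trials, trace=trace)


def simulate_cohort(
    config: GeneratorConfig,
    n_sessions: int,
    seed: int | np.random.SeedSequence,
    tracking: bool = False,
) -> list[SimulatedSession]:
    """Generate ``n_sessions`` independent sessions (seeds spawned from one
    root seed, one per subject)."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_sessions)
    return [
        simulate_session(
            config, child, session_id=f"{config.condition_label}-s{i:02d}", tracking=tracking
        )
        for i, child in enumerate(children)
    ]
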