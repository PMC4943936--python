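"""Two-state Markov description of cued responding.

Each trial is coded R+ (responded) or R- (not responded). Counting all
consecutive couplets gives the empirical right-stochastic transition matrix

    P(ab) = N(ab) / N(a),   a, b in {R+, R-},

where N(a) counts occurrences of *a* as the first member of a couplet. The
chain's stationary probability vector pi estimates the steady-state occupancy
of the responsive and non-responsive states; the difference of its two
components (pi_responsive - pi_nonresponsive) is the scalar summary compared
across conditions and session hours.

For a 2x2 chain the stationary vector has the closed form
pi_responsive = P(R-R+) / (P(R+R-) + P(R-R+)); the left-eigenvector route is
equivalent and serves as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .session import TrialRecord

__all__ = [
    "TransitionMatrix",
    "StationaryVector",
    "count_transitions",
    "transition_matrix_from_counts",
    "stationary_vector",
    "hourly_state_summary",
]

R_PLUS, R_MINUS = 0, 1
_STATE_NAMES = ("R+", "R-")


@dataclass(frozen=True)
class TransitionMatrix:
    """Couplet counts and conditional probabilities of the R+/R- chain.

    ``counts[a, b]`` is the number of consecutive trial pairs (a, b); rows
    are indexed by the antecedent. Rows whose antecedent never occurs as a
    couplet first member are *undefined* (probabilities NaN, never imputed
    as zero).
    """

    counts: np.ndarray
    probs: np.ndarray
    n_pairs: int
    undefined_rows: frozenset = field(default_factory=frozenset)

    def row_defined(self, state: int) -> bool:
        return _STATE_NAMES[state] not in self.undefined_rows


@dataclass(frozen=True)
class StationaryVector:
    """Steady-state occupancy (pi_responsive, pi_nonresponsive).

    ``diff = pi_responsive - pi_nonresponsive`` (equivalently
    2*pi_responsive - 1). ``degenerate`` marks chains without a unique
    stationary law (two absorbing states) or single-state blocks resolved by
    convention; ``note`` explains which.
    """

    pi: tuple[float, float]
    diff: float
    degenerate: bool = False
    note: str = ""


def transition_matrix_from_counts(counts: np.ndarray) -> TransitionMatrix:
    """Build the probability matrix from raw couplet counts."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (2, 2):
        raise ValueError("counts must be 2x2")
    row_totals = counts.sum(axis=1)
    probs = np.full((2, 2), np.nan)
    undefined = []
    for a in (R_PLUS, R_MINUS):
        if row_totals[a] > 0:
            probs[a] = counts[a] / row_totals[a]
        else:
            undefined.append(_STATE_NAMES[a])
    return TransitionMatrix(
        counts=counts,
        probs=probs,
        n_pairs=int(counts.sum()),
        undefined_rows=frozenset(undefined),
    )


def count_transitions(sequence: Sequence[bool | int]) -> TransitionMatrix:
    """Count R+/R- couplets over all consecutive trial pairs.

    ``sequence`` holds per-trial responded flags (truthy = R+). The
    denominator of each row counts that state's occurrences as a couplet
    first member, so a final-position occurrence does not enter its row
    total. Sequences shorter than two trials have no couplets and raise.
    """
    flags = np.asarray([bool(x) for x in sequence])
    if flags.size < 2:
        raise ValueError("need at least 2 trials to count transitions")
    a = np.where(flags[:-1], R_PLUS, R_MINUS)
    b = np.where(flags[1:], R_PLUS, R_MINUS)
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return transition_matrix_from_counts(counts)


def stationary_vector(tm: TransitionMatrix) -> StationaryVector:
    """Stationary occupancy of a fully observed 2x2 chain (closed form).

    Uses pi_responsive = P(R-R+) / (P(R+R-) + P(R-R+)). Two absorbing
    states (both off-diagonals zero) have no unique stationary law: the
    result is flagged degenerate with NaN components. A period-2 chain (both
    off-diagonals one) yields (0.5, 0.5), the time-average occupancy. An
    undefined row raises; pool over a longer window instead.
    """
    if tm.undefined_rows:
        raise ValueError(
            f"row(s) {sorted(tm.undefined_rows)} undefined (antecedent never "
            "observed); pool trials over the whole session instead"
        )
    p = float(tm.probs[R_PLUS, R_MINUS])   # leave responsive
    q = float(tm.probs[R_MINUS, R_PLUS])   # enter responsive
    if p == 0.0 and q == 0.0:
        return StationaryVector(
            pi=(float("nan"), float("nan")),
            diff=float("nan"),
            degenerate=True,
            note="two absorbing states: stationary law not unique",
        )
    pi_plus = q / (p + q)
    note = "period-2 chain: pi is the time-average occupancy" if p == q == 1.0 else ""
    return StationaryVector(pi=(pi_plus, 1.0 - pi_plus), diff=2.0 * pi_plus - 1.0, note=note)


def _block_stationary(tm: TransitionMatrix) -> StationaryVector:
    """Stationary vector with the single-state-block convention applied."""
    if not tm.undefined_rows:
        return stationary_vector(tm)
    if "R+" in tm.undefined_rows and "R-" in tm.undefined_rows:
        return StationaryVector(
            (float("nan"), float("nan")), float("nan"), True, "no couplets"
        )
    # all couplet firsts are one state: occupancy pinned there by convention
    if "R-" in tm.undefined_rows:
        return StationaryVector((1.0, 0.0), 1.0, True, "all-R+ block")
    return StationaryVector((0.0, 1.0), -1.0, True, "all-R- block")


def hourly_state_summary(
    trials: Sequence[TrialRecord],
    hour_edges: Sequence[float] = (0.0, 3600.0, 7200.0),
) -> pd.DataFrame:
    """Per-hour transition matrices and stationary vectors.

    A couplet straddling an hour boundary is assigned to the block holding
    its FIRST trial's cue onset (the couplet conditions on the antecedent).
    Blocks with no couplets are marked insufficient. Single-state blocks
    (floor/ceiling sessions) get the conventional degenerate pi of
    (1, 0) or (0, 1).

    Returns one row per block with columns ``hour, n_trials, n_pairs,
    insufficient, p_pp, p_pm, p_mp, p_mm, pi_plus, pi_minus, diff,
    degenerate`` plus the matrix/vector objects in ``tm`` and ``sv``.
    """
    trials = list(trials)
    edges = np.asarray(hour_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least two hour edges")
    onsets = np.array([t.cue_onset for t in trials])
    flags = np.array([t.responded for t in trials], dtype=bool)
    rows = []
    for h in range(edges.size - 1):
        lo, hi = edges[h], edges[h + 1]
        in_block = (onsets >= lo) & (onsets < hi)
        counts = np.zeros((2, 2), dtype=np.int64)
        for k in np.flatnonzero(in_block):
            if k + 1 >= len(trials):
                continue
            a = R_PLUS if flags[k] else R_MINUS
            b = R_PLUS if flags[k + 1] else R_MINUS
            counts[a, b] += 1
        n_pairs = int(counts.sum())
        insufficient = n_pairs == 0
        tm = transition_matrix_from_counts(counts)
        sv = (
            StationaryVector((float("nan"),) * 2, float("nan"), True, "insufficient")
            if insufficient
            else _block_stationary(tm)
        )
        rows.append(
            dict(
                hour=h,
                n_trials=int(in_block.sum()),
                n_pairs=n_pairs,
                insufficient=insufficient,
                p_pp=tm.probs[0, 0], p_pm=tm.probs[0, 1],
                p_mp=tm.probs[1, 0], p_mm=tm.probs[1, 1],
                pi_plus=sv.pi[0], pi_minus=sv.pi[1],
                diff=sv.diff, degenerate=sv.degenerate,
                tm=tm, sv=sv,
            )
        )
    return pd.DataFrame(rows)
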