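"""Transition counting and stationary vectors against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuedapproach.markov import (
    count_transitions,
    hourly_state_summary,
    stationary_vector,
    transition_matrix_from_counts,
)
from tests.test_response_metrics import make_trials


def stationary_by_eigenvector(probs: np.ndarray) -> np.ndarray:
    """Oracle: left eigenvector of the transition matrix at eigenvalue 1,
    normalized to sum to one."""
    vals, vecs = np.linalg.eig(probs.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    return v / v.sum()


def stationary_by_matrix_power(probs: np.ndarray, k: int = 200) -> np.ndarray:
    """Oracle: rows of probs^k converge to the stationary law."""
    return np.linalg.matrix_power(probs, k)[0]


def test_couplet_counts_by_hand():
    # [R+, R+, R-, R-, R+] -> pairs ++, +-, --, -+
    tm = count_transitions([1, 1, 0, 0, 1])
    np.testing.assert_array_equal(tm.counts, [[1, 1], [1, 1]])
    np.testing.assert_allclose(tm.probs, 0.5)
    assert tm.n_pairs == 4
    assert not tm.undefined_rows


def test_single_state_sequence_leaves_other_row_undefined():
    tm = count_transitions([1, 1, 1, 1])
    assert tm.probs[0, 0] == 1.0
    assert "R-" in tm.undefined_rows
    assert np.isnan(tm.probs[1]).all()


def test_minimal_two_trial_sequence():
    tm = count_transitions([1, 0])
    assert tm.probs[0, 1] == 1.0
    assert tm.undefined_rows == {"R-"}
    with pytest.raises(ValueError, match="pool"):
        stationary_vector(tm)


def test_too_short_sequence_rejected():
    with pytest.raises(ValueError):
        count_transitions([1])


def test_denominator_excludes_final_position():
    """N(a) counts occurrences as couplet FIRST member only."""
    tm = count_transitions([0, 1, 1])  # pairs: -+, ++
    np.testing.assert_array_equal(tm.counts, [[1, 0], [1, 0]])
    assert tm.probs[0, 0] == 1.0  # one R+ first (index 1), not two


def test_transition_counts_match_enumeration_on_all_short_sequences():
    """Exhaustive pair-counting oracle on every sequence of length <= 10."""
    for n in range(2, 11):
        for flags in itertools.product([0, 1], repeat=n):
            tm = count_transitions(flags)
            expected = np.zeros((2, 2), dtype=int)
            for a, b in zip(flags, flags[1:]):
                expected[1 - a, 1 - b] += 1
            np.testing.assert_array_equal(tm.counts, expected)
            assert tm.n_pairs == n - 1


def test_symmetric_matrix_has_uniform_stationary_law():
    tm = transition_matrix_from_counts(np.array([[5, 5], [5, 5]]))
    sv = stationary_vector(tm)
    assert sv.pi == (0.5, 0.5)
    assert sv.diff == 0.0


def test_closed_form_matches_power_iteration_oracle():
    probs = np.array([[0.9, 0.1], [0.3, 0.7]])
    counts = (probs * np.array([[1000], [1000]])).astype(int)
    sv = stationary_vector(transition_matrix_from_counts(counts))
    assert sv.pi[0] == pytest.approx(0.75, abs=1e-12)
    assert sv.diff == pytest.approx(0.5, abs=1e-12)
    oracle = stationary_by_matrix_power(probs)
    np.testing.assert_allclose(sv.pi, oracle, atol=1e-10)


def test_period_two_chain_returns_time_average():
    tm = transition_matrix_from_counts(np.array([[0, 10], [10, 0]]))
    sv = stationary_vector(tm)
    assert sv.pi == (0.5, 0.5)
    assert "time-average" in sv.note
    oracle = stationary_by_eigenvector(tm.probs)
    np.testing.assert_allclose(sv.pi, oracle, atol=1e-12)


def test_two_absorbing_states_flagged_degenerate():
    tm = transition_matrix_from_counts(np.array([[10, 0], [0, 10]]))
    sv = stationary_vector(tm)
    assert sv.degenerate
    assert np.isnan(sv.diff)


@settings(max_examples=300, derandomize=True)
@given(
    p=st.floats(0.001, 1.0),
    q=st.floats(0.001, 1.0),
)
def test_closed_form_equals_eigenvector_route(p, q):
    """Random valid matrices: closed form vs eigen-decomposition to 1e-10."""
    probs = np.array([[1 - p, p], [q, 1 - q]])
    counts = np.rint(probs * 10_000).astype(int)
    tm = transition_matrix_from_counts(counts)
    sv = stationary_vector(tm)
    oracle = stationary_by_eigenvector(tm.probs)
    np.testing.assert_allclose(sv.pi, oracle, atol=1e-10)
    assert sv.pi[0] + sv.pi[1] == pytest.approx(1.0, abs=1e-12)
    assert sv.diff == pytest.approx(2 * sv.pi[0] - 1, abs=1e-12)


def test_diff_is_antisymmetric_under_state_relabeling():
    flags = [1, 1, 0, 1, 0, 0, 1, 1, 1, 0]
    sv = stationary_vector(count_transitions(flags))
    sv_flipped = stationary_vector(count_transitions([1 - f for f in flags]))
    assert sv.diff == pytest.approx(-sv_flipped.diff, abs=1e-12)


# ---------------------------------------------------------------------------
# hourly summaries
# ---------------------------------------------------------------------------

def test_hour_with_no_trials_is_insufficient():
    trials = make_trials([1, 0, 1, 0, 1], spacing=40.0)  # all within hour 1
    df = hourly_state_summary(trials, (0.0, 3600.0, 7200.0))
    assert not df.loc[0, "insufficient"]
    assert df.loc[1, "insufficient"]
    assert np.isnan(df.loc[1, "diff"])


def test_straddling_pair_assigned_to_first_trials_hour():
    from cuedapproach.session import TrialRecord

    # onsets 3590 and 3610: the couplet belongs to hour 0
    trials = [
        TrialRecord(0, "LARGE", 3590.0, 3592.0, 3590.0, True, 3592.0),
        TrialRecord(1, "LARGE", 3610.0, 3615.0, 18.0, False, None),
    ]
    df = hourly_state_summary(trials, (0.0, 3600.0, 7200.0))
    assert df.loc[0, "n_pairs"] == 1
    assert df.loc[0, "p_pm"] == 1.0
    assert df.loc[1, "n_pairs"] == 0 and df.loc[1, "insufficient"]


def test_all_responded_hour_gets_conventional_degenerate_pi():
    trials = make_trials([1] * 6, spacing=40.0)
    df = hourly_state_summary(trials, (0.0, 3600.0))
    assert df.loc[0, "degenerate"]
    assert df.loc[0, "pi_plus"] == 1.0 and df.loc[0, "diff"] == 1.0
    trials = make_trials([0] * 6, spacing=40.0)
    df = hourly_state_summary(trials, (0.0, 3600.0))
    assert df.loc[0, "pi_minus"] == 1.0 and df.loc[0, "diff"] == -1.0
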