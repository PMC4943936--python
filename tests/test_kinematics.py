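"""Centroid pipeline, movement thresholding and trial-locked metrics."""

import numpy as np
import pytest

from cuedapproach.kinematics import (
    LOG_SD_EPS,
    CentroidTrace,
    UnimodalDataError,
    approach_metrics,
    compute_centroid,
    fit_movement_threshold,
    iti_locomotion,
    receptacle_entry_rate,
    response_by_iti_bin,
    rolling_log_sd,
    segment_movement,
    weighted_gaussian_intersection,
)
from cuedapproach.session import Event, SessionEvents, TrackingTrace, TrialRecord


def make_trace(red, green, cm_per_pixel=1.0, fr=30.0):
    return TrackingTrace(fr, np.asarray(red, float), np.asarray(green, float), cm_per_pixel)


def centroid_from_xy(xy, fr=30.0, valid=None):
    xy = np.asarray(xy, float)
    if valid is None:
        valid = np.ones(len(xy), bool)
    return CentroidTrace(frame_rate=fr, xy=xy, valid=np.asarray(valid, bool))


# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------

def test_centroid_is_led_midpoint():
    trace = make_trace([[0.0, 0.0]] * 3, [[2.0, 4.0]] * 3)
    ct = compute_centroid(trace)
    np.testing.assert_allclose(ct.xy, [[1.0, 2.0]] * 3)
    assert ct.valid.all()


def test_short_gap_linearly_interpolated():
    """5 missing frames between x=0 and x=5 interpolate at 5/6 spacing."""
    n = 7
    red = np.full((n, 2), np.nan)
    red[0] = [0.0, 0.0]
    red[6] = [5.0, 0.0]
    ct = compute_centroid(make_trace(red, red))
    np.testing.assert_allclose(
        ct.xy[1:6, 0], [5 / 6, 10 / 6, 15 / 6, 20 / 6, 25 / 6], atol=1e-9
    )
    assert ct.valid.all()


def test_ten_frame_gap_interpolated_eleven_not():
    for gap, expect_valid in [(10, True), (11, False)]:
        n = gap + 2
        red = np.full((n, 2), np.nan)
        red[0] = [0.0, 0.0]
        red[-1] = [1.0, 1.0]
        ct = compute_centroid(make_trace(red, red))
        assert ct.valid[1:-1].all() == expect_valid
        if not expect_valid:
            assert np.isnan(ct.xy[1:-1]).all()


def test_single_missing_led_makes_frame_missing():
    red = [[0.0, 0.0], [np.nan, np.nan], [2.0, 2.0]]
    green = [[1.0, 1.0], [1.0, 1.0], [3.0, 3.0]]
    ct = compute_centroid(make_trace(red, green))
    # one-frame gap interpolates between the flanking centroids
    np.testing.assert_allclose(ct.xy[1], [(0.5 + 2.5) / 2, (0.5 + 2.5) / 2])


def test_edge_gaps_are_invalid():
    red = np.full((6, 2), np.nan)
    red[2:4] = [[1.0, 1.0], [2.0, 2.0]]
    ct = compute_centroid(make_trace(red, red))
    assert not ct.valid[0] and not ct.valid[-1]


def test_interpolated_points_stay_between_anchors():
    rng = np.random.default_rng(0)
    xy = np.cumsum(rng.normal(size=(50, 2)), axis=0)
    red = xy.copy()
    red[10:17] = np.nan
    ct = compute_centroid(make_trace(red, red))
    lo = np.minimum(xy[9], xy[17])
    hi = np.maximum(xy[9], xy[17])
    assert ((ct.xy[10:17] >= lo - 1e-9) & (ct.xy[10:17] <= hi + 1e-9)).all()


# ---------------------------------------------------------------------------
# rolling log-SD
# ---------------------------------------------------------------------------

def test_stationary_trace_gives_log_epsilon():
    ct = centroid_from_xy(np.ones((30, 2)))
    out = rolling_log_sd(ct)
    interior = out[3:-3]
    np.testing.assert_allclose(interior, np.log(LOG_SD_EPS), atol=1e-12)


def test_collinear_spacing_closed_form():
    """Centroids on a line at spacing d: the 7 distances from the window mean
    are (3d,2d,d,0,d,2d,3d); population SD = d*sqrt(52)/7."""
    d = 0.25
    xy = np.column_stack([np.arange(40) * d, np.zeros(40)])
    out = rolling_log_sd(centroid_from_xy(xy))
    dists = np.array([3, 2, 1, 0, 1, 2, 3]) * d
    expected_sd = dists.std()
    assert expected_sd == pytest.approx(d * np.sqrt(52) / 7, abs=1e-12)
    np.testing.assert_allclose(out[3:-3], np.log(expected_sd + LOG_SD_EPS), atol=1e-9)


def test_invalid_frames_poison_their_windows():
    xy = np.ones((30, 2))
    valid = np.ones(30, bool)
    valid[10] = False
    out = rolling_log_sd(centroid_from_xy(xy, valid=valid))
    assert np.isnan(out[7:14]).all()
    assert np.isfinite(out[3:7]).all() and np.isfinite(out[14:-3]).all()


def test_alternating_jitter_and_bouts_is_bimodal():
    """Constructed two-regime trace produces two well-separated log-SD modes."""
    rng = np.random.default_rng(9)
    segs = []
    pos = np.zeros(2)
    for k in range(60):
        if k % 2 == 0:
            segs.append(pos + rng.normal(0, 0.05, size=(60, 2)))
        else:
            step = rng.normal(0, 1, 2)
            step = 0.7 * step / np.linalg.norm(step)
            seg = pos + np.cumsum(np.tile(step, (30, 1)), axis=0)
            segs.append(seg + rng.normal(0, 0.05, size=(30, 2)))
            pos = seg[-1]
    xy = np.vstack(segs)
    out = rolling_log_sd(centroid_from_xy(xy))
    vals = out[np.isfinite(out)]
    seg_fit = fit_movement_threshold(vals)
    assert seg_fit.means[1] - seg_fit.means[0] > 1.0
    assert min(seg_fit.weights) > 0.1


@pytest.mark.parametrize("method", ["meandist", "step", "pairwise"])
def test_alternative_window_statistics_available(method):
    rng = np.random.default_rng(4)
    xy = np.cumsum(rng.normal(0, 0.1, size=(50, 2)), axis=0)
    out = rolling_log_sd(centroid_from_xy(xy), method=method)
    assert np.isfinite(out[3:-3]).all()


# ---------------------------------------------------------------------------
# mixture threshold
# ---------------------------------------------------------------------------

def test_threshold_recovers_analytic_intersection_equal_weights():
    rng = np.random.default_rng(11)
    x = np.concatenate([rng.normal(-2, 0.3, 50_000), rng.normal(0, 0.4, 50_000)])
    seg = fit_movement_threshold(x)
    analytic = weighted_gaussian_intersection(-2, 0.3, 0.5, 0, 0.4, 0.5)
    assert seg.threshold == pytest.approx(analytic, abs=0.05)


def test_threshold_shifts_toward_minor_mode_with_unequal_weights():
    rng = np.random.default_rng(12)
    x = np.concatenate([rng.normal(-2, 0.3, 90_000), rng.normal(0, 0.4, 10_000)])
    seg = fit_movement_threshold(x)
    analytic_eq = weighted_gaussian_intersection(-2, 0.3, 0.5, 0, 0.4, 0.5)
    analytic_w = weighted_gaussian_intersection(-2, 0.3, 0.9, 0, 0.4, 0.1)
    assert analytic_w > analytic_eq  # heavier lower mode pushes cut upward
    assert seg.threshold == pytest.approx(analytic_w, abs=0.05)


def test_threshold_accuracy_across_random_separated_mixtures():
    """Within 0.05 of the analytic density intersection whenever the means
    are >= 2 pooled SDs apart, across 20 seeds."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        s1, s2 = rng.uniform(0.2, 0.5, 2)
        sep = 2.0 * (s1 + s2) / 2 + rng.uniform(0.5, 2.0)
        m1, m2 = -1.0, -1.0 + sep
        w1 = rng.uniform(0.25, 0.75)
        n = 40_000
        n1 = int(round(w1 * n))
        x = np.concatenate(
            [rng.normal(m1, s1, n1), rng.normal(m2, s2, n - n1)]
        )
        seg = fit_movement_threshold(x)
        analytic = weighted_gaussian_intersection(m1, s1, n1 / n, m2, s2, 1 - n1 / n)
        assert seg.threshold == pytest.approx(analytic, abs=0.05), seed


def test_unimodal_data_raises():
    rng = np.random.default_rng(13)
    x = rng.normal(0, 0.5, 10_000)
    with pytest.raises((UnimodalDataError, ValueError)):
        fit_movement_threshold(x)
    with pytest.raises(ValueError):
        fit_movement_threshold(np.zeros(100))  # too few / constant


# ---------------------------------------------------------------------------
# bout segmentation
# ---------------------------------------------------------------------------

def test_seven_frames_is_no_bout_eight_is():
    base = np.full(40, -5.0)
    seven = base.copy()
    seven[10:17] = 1.0
    assert segment_movement(seven, 0.0) == []
    eight = base.copy()
    eight[10:18] = 1.0
    assert segment_movement(eight, 0.0) == [(10, 18)]


def test_invalid_frame_breaks_runs():
    x = np.full(40, 1.0)
    x[:5] = -5.0
    x[25] = np.nan
    x[33:] = -5.0
    # runs: [5,25) length 20 -> bout; [26,33) length 7 -> none
    assert segment_movement(x, 0.0) == [(5, 25)]


def test_bout_frames_are_supra_threshold_and_complement_has_no_run():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 500)
    bouts = segment_movement(x, 0.5)
    mask = np.zeros(500, bool)
    for b0, b1 in bouts:
        assert (x[b0:b1] > 0.5).all()
        assert b1 - b0 >= 8
        mask[b0:b1] = True
    outside = np.isfinite(x) & (x > 0.5) & ~mask
    assert segment_movement(np.where(outside, 1.0, -1.0), 0.0) == []


# ---------------------------------------------------------------------------
# approach metrics
# ---------------------------------------------------------------------------

def responded_trial(onset, entry, index=0):
    return TrialRecord(index, "LARGE", onset, entry, onset, True, entry)


def test_straight_approach_has_unit_efficiency():
    fr = 30.0
    n = 120
    xy = np.tile([0.0, 0.0], (n, 1))
    # straight line from (0,0) to (10,0) between frames 30 and 90
    xy[30:91, 0] = np.linspace(0, 10, 61)
    xy[91:, 0] = 10.0
    ct = centroid_from_xy(xy, fr=fr)
    seg = type("S", (), {"bouts": [(25, 91)]})()  # bout already running at onset
    trial = responded_trial(onset=1.0, entry=3.0)
    df = approach_metrics([trial], ct, seg, receptacle=(10.0, 0.0))
    assert df.loc[0, "path_efficiency"] == pytest.approx(1.0, abs=0.02)
    assert df.loc[0, "movement_onset_latency"] == pytest.approx(0.0)
    assert df.loc[0, "moving_at_cue"]
    assert df.loc[0, "receptacle_latency"] == pytest.approx(2.0)


def test_doubling_back_halves_efficiency():
    fr = 30.0
    xy = np.zeros((120, 2))
    # out to x=10 then back to 5, then to receptacle at 5: path 15, straight 5
    leg1 = np.linspace(0, 10, 31)
    leg2 = np.linspace(10, 5, 16)
    xy[30:61, 0] = leg1
    xy[61:77, 0] = leg2
    xy[77:, 0] = 5.0
    ct = centroid_from_xy(xy, fr=fr)
    seg = type("S", (), {"bouts": [(30, 77)]})()
    trial = responded_trial(onset=1.0, entry=77 / 30.0)
    df = approach_metrics([trial], ct, seg, receptacle=(5.0, 0.0))
    assert df.loc[0, "path_length"] == pytest.approx(15.0, abs=1e-6)
    assert df.loc[0, "path_efficiency"] == pytest.approx(5.0 / 15.0, abs=1e-6)


def test_l_shaped_path_pythagorean_efficiency():
    """Legs 3 and 4 cm to a receptacle 5 cm away: efficiency 5/7."""
    fr = 30.0
    xy = np.zeros((150, 2))
    xy[:30] = [0.0, 0.0]
    xy[30:61, 0] = np.linspace(0, 3, 31)         # leg 1: 3 cm in x
    xy[61:91, 0] = 3.0
    xy[61:91, 1] = np.linspace(4 / 30, 4, 30)    # leg 2: 4 cm in y
    xy[91:] = [3.0, 4.0]
    ct = centroid_from_xy(xy, fr=fr)
    seg = type("S", (), {"bouts": [(30, 91)]})()
    trial = responded_trial(onset=0.5, entry=3.0)
    df = approach_metrics([trial], ct, seg, receptacle=(3.0, 4.0))
    assert df.loc[0, "path_length"] == pytest.approx(7.0, abs=1e-6)
    assert df.loc[0, "path_efficiency"] == pytest.approx(5.0 / 7.0, abs=1e-6)
    # movement starts at frame 30 = 1.0 s, 0.5 s after cue onset
    assert df.loc[0, "movement_onset_latency"] == pytest.approx(0.5, abs=1e-9)
    assert not df.loc[0, "moving_at_cue"]


def test_invalid_tracking_excludes_trial_with_reason():
    xy = np.zeros((120, 2))
    valid = np.ones(120, bool)
    valid[50:70] = False
    ct = centroid_from_xy(xy, valid=valid)
    seg = type("S", (), {"bouts": []})()
    trial = responded_trial(onset=1.0, entry=3.0)
    df = approach_metrics([trial], ct, seg, receptacle=(5.0, 5.0))
    assert df.loc[0, "excluded"]
    assert "invalid" in df.loc[0, "exclude_reason"]


# ---------------------------------------------------------------------------
# ITI locomotion / entry rates / ITI bins
# ---------------------------------------------------------------------------

def test_stationary_iti_travels_zero():
    xy = np.ones((1300, 2))
    ct = centroid_from_xy(xy)
    trial = TrialRecord(0, "LARGE", 40.0, 42.0, 40.0, True, 42.0)
    df = iti_locomotion([trial], ct)
    assert df.loc[0, "iti_distance"] == pytest.approx(0.0)


def test_single_bout_iti_distance_and_rate():
    """One 1-s bout at 20 cm/s inside a 40-s ITI: 20 cm, 0.5 cm/s."""
    fr = 30.0
    n = int(45 * fr)
    xy = np.zeros((n, 2))
    b0 = int(10 * fr)
    xy[b0 : b0 + 31, 0] = np.linspace(0, 20, 31)
    xy[b0 + 31 :, 0] = 20.0
    ct = centroid_from_xy(xy, fr=fr)
    trial = TrialRecord(0, "LARGE", 40.0, 42.0, 40.0, False, None)
    df = iti_locomotion([trial], ct)
    assert df.loc[0, "iti_distance"] == pytest.approx(20.0, rel=0.01)
    assert df.loc[0, "iti_rate"] == pytest.approx(0.5, rel=0.01)
    assert not df.loc[0, "next_trial_responded"]


def test_entry_rate_counts_and_half_open_convention():
    """10 rewarded trials, one cued entry each, none pre-cue: post 0.2 Hz.
    An entry exactly at cue onset is post-cue, not pre-cue."""
    events = []
    trials = []
    t = 0.0
    for k in range(10):
        t += 30.0
        events.append(Event(t, "CUE_ON", "LARGE"))
        entry = t if k == 0 else t + 1.0  # first entry exactly at onset
        events.append(Event(entry, "ENTRY"))
        events.append(Event(entry, "CUE_OFF"))
        events.append(Event(entry, "REWARD", 250.0))
        events.append(Event(entry + 2.0, "EXIT"))
        trials.append(TrialRecord(k, "LARGE", t, entry, 30.0, True, entry))
        t = entry + 2.0
    session = SessionEvents("s", "", 600.0, events)
    pre, post = receptacle_entry_rate(trials, session)
    assert pre == 0.0
    assert post == pytest.approx(10 / (10 * 5.0))


def test_entry_rate_undefined_without_rewarded_trials():
    session = SessionEvents("s", "", 10.0, [])
    trial = TrialRecord(0, "LARGE", 5.0, 10.0, 5.0, False, None)
    pre, post = receptacle_entry_rate([trial], session)
    assert np.isnan(pre) and np.isnan(post)


def test_iti_bins_bucket_by_preceding_interval():
    trials = [
        TrialRecord(i, "LARGE", 100.0 * (i + 1), 100.0 * (i + 1) + 2, 35.0, i % 2 == 0,
                    100.0 * (i + 1) + 2 if i % 2 == 0 else None)
        for i in range(6)
    ]
    df = response_by_iti_bin(trials)
    occupied = df[df["n_trials"] > 0]
    assert list(occupied["bin_start"]) == [30.0]
    assert occupied.iloc[0]["n_trials"] == 6
    assert occupied.iloc[0]["ratio_pct"] == pytest.approx(50.0)
    assert np.isnan(df[df["bin_start"] == 0.0]["ratio_pct"]).all()
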