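"""Strip profiles, block classification, tracking and the deviation statistic."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rowmap as rm
from rowmap.row_tracking import Block, StripProfile

from conftest import make_bar_mask


# ---------------------------------------------------------------------------
# strips and profiles
# ---------------------------------------------------------------------------

def test_strip_scanlines_288():
    assert rm.strip_scanlines(288, 4).tolist() == [36.0, 108.0, 180.0, 252.0]


def test_strip_remainder_goes_to_bottom():
    from rowmap.row_tracking import strip_bounds

    assert strip_bounds(290, 4) == [(0, 72), (72, 144), (144, 216), (216, 290)]


def test_too_many_strips_rejected():
    with pytest.raises(ValueError):
        rm.compute_strip_profiles(np.zeros((3, 10)), 4)


def test_profile_fill_counts():
    mask = np.zeros((288, 10), np.uint8)
    mask[:, 2] = 1              # full column
    mask[0:36, 5] = 1           # top half of strip 0 only
    profs = rm.compute_strip_profiles(mask)
    assert all(p.fill[2] == 1.0 for p in profs)
    assert profs[0].fill[5] == pytest.approx(0.5)
    assert profs[1].fill[5] == 0.0


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def _profile(fill):
    return StripProfile(0, 36.0, np.asarray(fill, dtype=float))


def test_blocks_examples():
    fill = np.zeros(300)
    fill[100:130] = 1.0
    fill[240:246] = 1.0
    blocks = rm.profile_to_blocks(_profile(fill), 0.5)
    assert [(b.start_col, b.end_col, b.width) for b in blocks] == [
        (100, 130, 30),
        (240, 246, 6),
    ]
    assert rm.profile_to_blocks(_profile(np.zeros(50)), 0.5) == []
    one = np.zeros(50)
    one[7] = 0.9
    assert [(b.start_col, b.end_col) for b in rm.profile_to_blocks(_profile(one), 0.5)] == [(7, 8)]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_blocks_match_naive_run_scan(seed):
    rng = np.random.default_rng(seed)
    fill = rng.random(80)
    blocks = rm.profile_to_blocks(_profile(fill), 0.5)
    # naive scan
    runs, start = [], None
    for i, v in enumerate(fill):
        if v >= 0.5 and start is None:
            start = i
        if v < 0.5 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(fill)))
    assert [(b.start_col, b.end_col) for b in blocks] == runs


def test_merge_close_blocks_bridges_small_gaps():
    blocks = [Block(10, 24), Block(25, 31), Block(50, 60)]
    merged = rm.merge_close_blocks(blocks, 3)
    assert [(b.start_col, b.end_col) for b in merged] == [(10, 31), (50, 60)]


# ---------------------------------------------------------------------------
# center picking
# ---------------------------------------------------------------------------

def _blocks_at(centers, width):
    return [Block(int(c - width / 2), int(c + width / 2)) for c in centers]


def test_pick_exact_hits():
    blocks = _blocks_at([220, 360, 500], 30)
    got = rm.pick_row_centers(blocks, [220, 360, 500], 40, 10)
    assert got.tolist() == [220.0, 360.0, 500.0]


def test_pick_ignores_narrow_weed_block():
    blocks = _blocks_at([220, 360, 500], 30) + [Block(298, 303)]
    got = rm.pick_row_centers(blocks, [220, 360, 500], 40, 10)
    assert got.tolist() == [220.0, 360.0, 500.0]


def test_pick_missing_middle():
    blocks = _blocks_at([220, 500], 30)
    got = rm.pick_row_centers(blocks, [220, 360, 500], 40, 10)
    assert got[0] == 220.0 and np.isnan(got[1]) and got[2] == 500.0


def test_pick_conflict_nearer_expected_wins():
    blocks = [Block(285, 315)]  # center 300, reachable from 280 and 330
    got = rm.pick_row_centers(blocks, [280, 330, 500], 40, 10)
    # 280 is nearer to the block center than 330: it wins, 330 goes missing
    assert got[0] == 300.0 and np.isnan(got[1]) and np.isnan(got[2])


def test_pick_subpixel_centroid_with_fill():
    fill = np.zeros(100)
    fill[40:50] = 1.0
    fill[50:54] = 0.5  # asymmetric shoulder drags the centroid right
    blocks = rm.profile_to_blocks(_profile(fill), 0.5)
    got = rm.pick_row_centers(blocks, [46.0], 20, 5, fill=fill)
    expected = (np.arange(40, 54) + 0.5) @ fill[40:54] / fill[40:54].sum()
    assert got[0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# line fitting
# ---------------------------------------------------------------------------

def test_fit_vertical_row():
    m, c = rm.fit_row_line([(36, 220), (108, 220), (180, 220), (252, 220)])
    assert m == pytest.approx(0.0, abs=1e-12)
    assert c == pytest.approx(220.0)


def test_fit_diagonal():
    m, c = rm.fit_row_line([(0, 0), (10, 10)])
    assert m == pytest.approx(1.0) and c == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_normal_equations():
    rng = np.random.default_rng(4)
    y = np.array([36.0, 108.0, 180.0, 252.0])
    x = 0.13 * y + 241.0 + rng.normal(0, 0.5, 4)
    m, c = rm.fit_row_line(np.column_stack([y, x]))
    # hand-rolled normal equations for x = m*y + c
    A = np.array([[np.sum(y * y), np.sum(y)], [np.sum(y), len(y)]])
    b = np.array([np.sum(x * y), np.sum(x)])
    m_ref, c_ref = np.linalg.solve(A, b)
    assert m == pytest.approx(m_ref, abs=1e-9)
    assert c == pytest.approx(c_ref, abs=1e-9)


def test_fit_needs_two_distinct_y():
    with pytest.raises(ValueError):
        rm.fit_row_line([(36, 220)])
    with pytest.raises(ValueError):
        rm.fit_row_line([(36, 220), (36, 230)])


# ---------------------------------------------------------------------------
# tracker
# ---------------------------------------------------------------------------

def test_initialize_on_ideal_bars():
    state = rm.initialize_tracker(make_bar_mask())
    assert np.allclose(state.last_centers[0], 220.0, atol=0.5)
    assert np.allclose(state.last_centers[1], 360.0, atol=0.5)
    assert np.allclose(state.last_centers[2], 500.0, atol=0.5)


def test_initialize_blank_mask_fails():
    with pytest.raises(rm.TrackerInitializationError):
        rm.initialize_tracker(np.zeros((288, 720), np.uint8))


def test_initialize_on_synthetic_matches_truth(clean_scene, segmented_first_frame):
    state = rm.initialize_tracker(segmented_first_frame)
    truth = clean_scene.truth_row_centers(0)
    assert np.abs(state.last_centers - truth).max() < 3.0


def test_track_fixed_point_on_identical_mask():
    mask = make_bar_mask()
    state = rm.initialize_tracker(mask)
    obs1, state = rm.track_frame(state, mask)
    obs2, _ = rm.track_frame(state, mask)
    assert obs1.found_mask.all() and obs2.found_mask.all()
    assert np.allclose(obs1.centers, obs2.centers)


def test_track_follows_lateral_shift():
    mask = make_bar_mask()
    state = rm.initialize_tracker(mask)
    obs0, state = rm.track_frame(state, mask)
    shifted = np.roll(mask, 8, axis=1)
    obs1, _ = rm.track_frame(state, shifted)
    assert obs1.found_mask.all()
    assert np.allclose(obs1.centers - obs0.centers, 8.0)


@settings(max_examples=12, derandomize=True, deadline=None)
@given(st.integers(-30, 30))
def test_shift_equivariance(d):
    """Shifting the mask by |d| < halfwidth shifts every found center by d."""
    mask = make_bar_mask()
    state = rm.initialize_tracker(mask)
    obs0, state0 = rm.track_frame(state, mask)
    obs1, _ = rm.track_frame(state0, np.roll(mask, d, axis=1))
    assert np.allclose(obs1.centers - obs0.centers, float(d), atol=1e-9)


def test_tracking_stays_ordered_and_bounded(clean_scene, clean_sequence):
    frames, truth = clean_sequence
    state = None
    prev = None
    hw = rm.TrackerParams().search_halfwidth_px
    for k in range(frames.shape[0]):
        mask = rm.segment_frame(frames[k])
        if k == 0:
            state = rm.initialize_tracker(mask)
        obs, state = rm.track_frame(state, mask)
        # ordering: left < middle < right in every strip
        assert (np.diff(obs.centers, axis=0) > 0).all()
        if prev is not None:
            step = np.abs(obs.centers - prev.centers)[obs.found_mask]
            assert (step <= hw + 1e-9).all()
        prev = obs


def test_tracking_matches_ground_truth(clean_sequence):
    frames, truth = clean_sequence
    state, errs = None, []
    for k in range(frames.shape[0]):
        mask = rm.segment_frame(frames[k])
        if k == 0:
            state = rm.initialize_tracker(mask)
        obs, state = rm.track_frame(state, mask)
        errs.append(np.abs(obs.centers - truth.row_centers_px[k]))
    errs = np.array(errs)
    assert (errs <= 3.0).mean() >= 0.99


# ---------------------------------------------------------------------------
# deviation statistic
# ---------------------------------------------------------------------------

def _obs(m, c, w=720):
    lines = np.array([[0.0, c - 140.0], [m, c], [0.0, c + 140.0]])
    return rm.RowObservation(
        frame_index=0,
        centers=np.zeros((3, 4)),
        lines=lines,
        found_mask=np.ones((3, 4), bool),
        strip_ys=np.array([36.0, 108.0, 180.0, 252.0]),
        image_w=w,
    )


def test_deviation_zero_for_centered_row():
    assert rm.central_row_deviation(_obs(0.0, 360.0)) == 0.0


def test_deviation_93px_is_66pct_of_spacing():
    dev = rm.central_row_deviation(_obs(0.0, 360.0 + 93.0))
    assert dev == pytest.approx(93.0)
    assert round(rm.deviation_fraction_of_spacing(dev, 140.0)) == 66


def test_deviation_line_evaluation():
    assert rm.central_row_deviation(_obs(0.1, 400.0), eval_y=215.0) == pytest.approx(61.5)


def test_deviation_stats_fields():
    s = rm.deviation_stats([-26.0, 10.0, 93.0])
    assert s["max_right_px"] == 93.0
    assert s["max_left_px"] == 26.0
    assert s["mean_abs_px"] == pytest.approx((26 + 10 + 93) / 3)


def test_deviation_tracks_known_sway(clean_sequence):
    """The deviation series correlates strongly with the true sway."""
    frames, truth = clean_sequence
    state, devs = None, []
    for k in range(frames.shape[0]):
        mask = rm.segment_frame(frames[k])
        if k == 0:
            state = rm.initialize_tracker(mask)
        obs, state = rm.track_frame(state, mask)
        devs.append(rm.central_row_deviation(obs))
    r = np.corrcoef(devs, -truth.lateral_offset_m)[0, 1]
    assert r > 0.95
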