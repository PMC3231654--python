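"""Shared fixtures: small synthetic sequences rendered once per session."""
import numpy as np
import pytest

import rowmap as rm


@pytest.fixture(scope="session")
def camera():
    return rm.CameraModel()


@pytest.fixture(scope="session")
def clean_spec():
    """Gap-free, weed-free field: the oracle setting for tracking accuracy."""
    return rm.SceneSpec(gap_prob=0.0, weed_rate=0.0, field_length_m=16.0, seed=7)


@pytest.fixture(scope="session")
def clean_scene(clean_spec, camera):
    sway = rm.SwayTrajectory.sinusoidal(20, 0.33 * 0.7, 60.0)
    return rm.SyntheticScene(clean_spec, camera, sway)


@pytest.fixture(scope="session")
def clean_sequence(clean_spec, camera):
    """20 frames with moderate sinusoidal sway, plus ground truth."""
    sway = rm.SwayTrajectory.sinusoidal(20, 0.33 * 0.7, 60.0)
    return rm.generate_sequence(clean_spec, camera, sway, 20)


@pytest.fixture(scope="session")
def weedy_scene(camera):
    """Static scene with plenty of weed blobs, for the morphology contract."""
    spec = rm.SceneSpec(
        gap_prob=0.0, weed_rate=1.5, field_length_m=14.0, seed=21
    )
    return rm.SyntheticScene(spec, camera, rm.SwayTrajectory.zero(2))


@pytest.fixture(scope="session")
def segmented_first_frame(clean_sequence):
    frames, _ = clean_sequence
    return rm.segment_frame(frames[0])


def make_bar_mask(
    h=288, w=720, centers=(220.0, 360.0, 500.0), halfwidth=12, dtype=np.uint8
):
    """Ideal mask of three vertical bars (straight rows seen without tilt)."""
    mask = np.zeros((h, w), dtype=dtype)
    for c in centers:
        mask[:, int(round(c - halfwidth)) : int(round(c + halfwidth))] = 1
    return mask
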