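"""Shared fixtures: small synthetic scripts, cohorts and sample streams."""

import numpy as np
import pandas as pd
import pytest

import gazeprox as gp
from gazeprox.reference import GridSpec

COARSE_GRID = GridSpec(1920, 1200, cell_size_px=32)


@pytest.fixture(scope="session")
def geometry():
    return gp.TOBII_TX300


@pytest.fixture(scope="session")
def small_script():
    """Single-focus 60-frame script (deterministic)."""
    return gp.make_scene_script(n_frames=60, seed=11, max_foci=1, n_cuts=2)


@pytest.fixture(scope="session")
def small_cohort(small_script):
    """8 reference-group recordings on the small script."""
    spec = gp.CohortSpec(n_subjects=8, noise_sd_px=60.0, dropout=0.05,
                         on_script=0.95)
    recs, truth = gp.generate_cohort_gaze(small_script, spec, seed=21)
    return recs, truth


@pytest.fixture(scope="session")
def small_reference(small_script, small_cohort):
    recs, _ = small_cohort
    return gp.build_reference(recs, small_script.timeline,
                              grid_spec=COARSE_GRID, min_points_per_frame=3)


def make_static_script(script):
    """Freeze every segment's foci at their segment-start positions."""
    import copy
    s = copy.deepcopy(script)
    bounds = [0] + list(s.cut_frames) + [s.n_frames]
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        for f in range(a, b):
            s.foci[f] = s.foci[a]
    return s


def make_stream(positions, hz=300.0, geometry=gp.TOBII_TX300,
                valid=None, t0=0.0):
    """Build a GazeRecording from an (n, 2) pixel position array."""
    positions = np.asarray(positions, float)
    n = len(positions)
    if valid is None:
        valid = np.ones(n, bool)
    t = t0 + np.arange(n) / hz
    samples = pd.DataFrame({
        "t": t,
        "left_x": positions[:, 0], "left_y": positions[:, 1],
        "right_x": positions[:, 0], "right_y": positions[:, 1],
        "left_valid": valid, "right_valid": valid,
    })
    return gp.GazeRecording(subject_id="s", group="test", age_years=3.0,
                            sampling_hz=hz, samples=samples,
                            geometry=geometry)
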