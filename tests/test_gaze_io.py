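"""Gaze I/O, geometry conversion, I-VT filtering, attendance, frame mapping."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import gazeprox as gp
from gazeprox.gaze import GazeDataError, GazeFormatError

from conftest import make_stream


# ---------------------------------------------------------------------------
# loading and validation

def _write_gaze(path, rows, header="t\tleft_x\tleft_y\tright_x\tright_y\tleft_valid\tright_valid"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestLoadRecording:
    def test_identity_readback(self, tmp_path, geometry):
        f = tmp_path / "g.tsv"
        _write_gaze(f, ["0.0\t100\t200\t110\t210\t1\t1",
                        "0.01\t101\t201\t111\t211\t1\t1",
                        "0.02\t102\t202\t112\t212\t1\t1"])
        rec = gp.load_gaze_recording(f, geometry, subject_id="a")
        assert rec.n_samples == 3
        assert rec.samples["left_x"].tolist() == [100, 101, 102]
        assert rec.binocular_valid().all()

    def test_offscreen_flagged_invalid_but_retained(self, tmp_path, geometry):
        f = tmp_path / "g.tsv"
        _write_gaze(f, ["0.0\t-50\t200\t110\t210\t1\t1",
                        "0.01\t100\t200\t110\t210\t1\t1"])
        rec = gp.load_gaze_recording(f, geometry)
        assert not rec.samples["left_valid"].iloc[0]      # x = -50 off-screen
        assert rec.samples["left_x"].iloc[0] == -50       # value retained
        assert rec.samples["right_valid"].iloc[0]

    def test_shuffled_timestamps_raise(self, tmp_path, geometry):
        f = tmp_path / "g.tsv"
        _write_gaze(f, ["0.02\t100\t200\t110\t210\t1\t1",
                        "0.00\t100\t200\t110\t210\t1\t1"])
        with pytest.raises(GazeDataError):
            gp.load_gaze_recording(f, geometry)

    def test_missing_column_raises(self, tmp_path, geometry):
        f = tmp_path / "g.tsv"
        f.write_text("t\tleft_x\n0\t1\n")
        with pytest.raises(GazeFormatError):
            gp.load_gaze_recording(f, geometry)

    def test_comma_delimiter_sniffed(self, tmp_path, geometry):
        f = tmp_path / "g.csv"
        f.write_text("t,left_x,left_y,right_x,right_y,left_valid,right_valid\n"
                     "0.0,100,200,110,210,1,1\n")
        assert gp.load_gaze_recording(f, geometry).n_samples == 1


# ---------------------------------------------------------------------------
# pixel <-> degree conversion

class TestAngleConversion:
    def test_zero_is_zero(self, geometry):
        assert gp.pixels_to_degrees(0.0, geometry) == 0.0

    def test_full_screen_extents(self, geometry):
        # the panel subtends 29 deg 38' vertically and 45 deg 53' horizontally
        assert gp.pixels_to_degrees(1200, geometry, axis="y") == pytest.approx(
            29 + 38 / 60, abs=1e-9)
        assert gp.pixels_to_degrees(1920, geometry, axis="x") == pytest.approx(
            45 + 53 / 60, abs=1e-9)

    def test_against_trigonometric_oracle(self, geometry):
        # independent closed form: screen physical size back-solved from the
        # stated angles, then the chord angle of a 5-degree displacement
        height_cm = 2 * 60.0 * math.tan(math.radians((29 + 38 / 60) / 2))
        px = 5.0  # degrees
        d_cm = 2 * 60.0 * math.tan(math.radians(px / 2))
        expected_px = d_cm / (height_cm / 1200)
        got = gp.degrees_to_pixels(5.0, geometry, axis="y")
        assert got == pytest.approx(expected_px, rel=1e-12)
        assert gp.pixels_to_degrees(got, geometry, axis="y") == pytest.approx(
            5.0, rel=1e-12)

    @pytest.mark.parametrize("px", [-700.0, -1.5, 0.0, 3.0, 911.0])
    def test_roundtrip_and_sign_symmetry(self, geometry, px):
        deg = gp.pixels_to_degrees(px, geometry, axis="x")
        assert gp.degrees_to_pixels(deg, geometry, axis="x") == pytest.approx(
            px, rel=1e-9, abs=1e-9)
        assert gp.pixels_to_degrees(-px, geometry, axis="x") == pytest.approx(
            -deg, abs=1e-12)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            gp.ScreenGeometry(1920, 1200, 45.9, 29.6, viewing_distance_cm=0)


# ---------------------------------------------------------------------------
# I-VT filter

def _ivt_oracle(rec, threshold=30.0, window_ms=20.0, merge_gap_ms=75.0,
                merge_angle=0.5):
    """Brute-force I-VT: label every sample by thresholded velocity (plain
    python loops, planar trig computed from scratch), scan for runs, merge."""
    geom = rec.geometry
    t = rec.samples["t"].to_numpy(float)
    xy = rec.midpoint_trace()
    n = len(t)

    def ang(p, q):
        dx = (p[0] - q[0]) * geom.cm_per_px_x
        dy = (p[1] - q[1]) * geom.cm_per_px_y
        return 2 * math.degrees(math.atan(math.hypot(dx, dy)
                                          / (2 * geom.viewing_distance_cm)))

    half = max(1, round(rec.sampling_hz * window_ms / 2000.0))
    labels = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        if t[hi] == t[lo] or np.isnan(xy[lo]).any() or np.isnan(xy[hi]).any():
            labels.append(False)
            continue
        labels.append(ang(xy[hi], xy[lo]) / (t[hi] - t[lo]) < threshold)
    runs = []
    i = 0
    while i < n:
        if labels[i]:
            j = i
            while j < n and labels[j]:
                j += 1
            if j - i >= 2:
                runs.append((i, j))
            i = j
        else:
            i += 1
    fixes = [dict(onset=t[a], offset=t[b - 1],
                  cx=float(xy[a:b, 0].mean()), cy=float(xy[a:b, 1].mean()),
                  n=b - a) for a, b in runs]
    merged = []
    for f in fixes:
        if merged:
            p = merged[-1]
            if (f["onset"] - p["offset"] <= merge_gap_ms / 1e3
                    and ang((p["cx"], p["cy"]), (f["cx"], f["cy"])) <= merge_angle):
                tot = p["n"] + f["n"]
                merged[-1] = dict(
                    onset=p["onset"], offset=f["offset"],
                    cx=(p["cx"] * p["n"] + f["cx"] * f["n"]) / tot,
                    cy=(p["cy"] * p["n"] + f["cy"] * f["n"]) / tot, n=tot)
                continue
        merged.append(dict(f))
    for i, f in enumerate(merged):
        f["amp"] = None if i == 0 else ang(
            (merged[i - 1]["cx"], merged[i - 1]["cy"]), (f["cx"], f["cy"]))
    return merged


def _two_cluster_stream(sep_deg=10.0, hz=300.0, hold_s=0.5, jump_samples=6):
    dx = gp.degrees_to_pixels(sep_deg, gp.TOBII_TX300, axis="x")
    a = np.tile([400.0, 600.0], (int(hold_s * hz), 1))
    b = np.tile([400.0 + dx, 600.0], (int(hold_s * hz), 1))
    ramp = np.linspace(a[-1], b[0], jump_samples + 2)[1:-1]
    return make_stream(np.vstack([a, ramp, b]), hz=hz)


class TestIVTFilter:
    def test_stationary_second_is_one_fixation(self):
        rec = make_stream(np.tile([500.0, 500.0], (300, 1)), hz=300.0)
        fixes = gp.ivt_fixation_filter(rec)
        assert len(fixes) == 1
        assert fixes[0].duration == pytest.approx(1.0, abs=0.02)
        assert fixes[0].preceding_saccade_amplitude is None

    def test_two_clusters_ten_degrees_apart(self):
        fixes = gp.ivt_fixation_filter(_two_cluster_stream())
        assert len(fixes) == 2
        assert fixes[1].preceding_saccade_amplitude == pytest.approx(10.0,
                                                                     abs=0.1)

    def test_small_displacement_gap_is_merged(self):
        # 50 ms tracking gap, 0.3 deg displacement: gap-filled and unified
        dx = gp.degrees_to_pixels(0.3, gp.TOBII_TX300, axis="x")
        hz = 300.0
        a = np.tile([500.0, 500.0], (150, 1))
        b = np.tile([500.0 + dx, 500.0], (150, 1))
        gap = np.full((15, 2), np.nan)  # 50 ms of lost tracking
        pos = np.vstack([a, gap, b])
        valid = np.isfinite(pos[:, 0])
        pos[~valid] = 0.0
        rec = make_stream(pos, hz=hz, valid=valid)
        fixes = gp.ivt_fixation_filter(rec)
        assert len(fixes) == 1

    def test_excursion_fixations_merged_by_rule(self):
        # a 30 ms saccadic excursion returning within 0.3 deg: the two raw
        # runs satisfy the 75 ms / 0.5 deg merge rule
        hz = 300.0
        far = gp.degrees_to_pixels(8.0, gp.TOBII_TX300, axis="x")
        small = gp.degrees_to_pixels(0.3, gp.TOBII_TX300, axis="x")
        a = np.tile([500.0, 500.0], (150, 1))
        out = np.linspace(500.0, 500.0 + far, 6)[1:]
        back = np.linspace(500.0 + far, 500.0 + small, 6)[1:-1]
        exc = np.column_stack([np.concatenate([out, back]),
                               np.full(9, 500.0)])
        b = np.tile([500.0 + small, 500.0], (150, 1))
        rec = make_stream(np.vstack([a, exc, b]), hz=hz)
        merged = gp.ivt_fixation_filter(rec)
        unmerged = gp.ivt_fixation_filter(rec, merge_max_angle_deg=-1.0)
        assert len(unmerged) >= 2
        assert len(merged) < len(unmerged)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random walk with occasional saccades
        pos = [np.array([960.0, 600.0])]
        for _ in range(599):
            step = rng.normal(0, 0.8, 2)
            if rng.random() < 0.02:
                step += rng.uniform(-300, 300, 2)
            pos.append(np.clip(pos[-1] + step, 10, 1100))
        rec = make_stream(np.array(pos), hz=300.0)
        got = gp.ivt_fixation_filter(rec)
        exp = _ivt_oracle(rec)
        assert len(got) == len(exp)
        for g, e in zip(got, exp):
            assert g.onset == pytest.approx(e["onset"], abs=1e-12)
            assert g.offset == pytest.approx(e["offset"], abs=1e-12)
            assert g.centroid_xy[0] == pytest.approx(e["cx"], abs=1e-9)
            if e["amp"] is None:
                assert g.preceding_saccade_amplitude is None
            else:
                assert g.preceding_saccade_amplitude == pytest.approx(
                    e["amp"], abs=1e-9)

    def test_deterministic_and_duration_bounded(self):
        rec = _two_cluster_stream()
        f1 = gp.ivt_fixation_filter(rec)
        f2 = gp.ivt_fixation_filter(rec)
        assert f1 == f2
        assert sum(f.duration for f in f1) <= rec.duration + 1e-9

    def test_all_invalid_warns_and_empty(self):
        pos = np.zeros((100, 2))
        rec = make_stream(pos, valid=np.zeros(100, bool))
        with pytest.warns(UserWarning):
            assert gp.ivt_fixation_filter(rec) == []


# ---------------------------------------------------------------------------
# screen attendance

class TestAttendance:
    def test_full_coverage_included(self):
        rec = make_stream(np.tile([500.0, 500.0], (300, 1)), hz=300.0)
        tl = gp.FrameTimeline(n_frames=25, fps=25.0)
        att = gp.screen_attendance(rec, tl)
        assert att.fraction == 1.0 and att.included

    def test_sixty_four_percent_excluded(self):
        # valid samples on exactly 64 of 100 frames -> below the 65% bar
        hz, fps, n_frames = 300.0, 25.0, 100
        n = int(n_frames / fps * hz)
        pos = np.tile([500.0, 500.0], (n, 1))
        t = np.arange(n) / hz
        frame = (t * fps).astype(int)
        valid = frame < 64
        rec = make_stream(pos, hz=hz, valid=valid)
        att = gp.screen_attendance(rec, gp.FrameTimeline(n_frames, fps))
        assert att.fraction == pytest.approx(0.64)
        assert not att.included

    def test_dropout_mask_oracle(self):
        rng = np.random.default_rng(5)
        hz, fps, n_frames = 300.0, 25.0, 50
        n = int(n_frames / fps * hz)
        frame_mask = rng.random(n_frames) < 0.7
        t = np.arange(n) / hz
        valid = frame_mask[(t * fps).astype(int)]
        rec = make_stream(np.tile([500.0, 500.0], (n, 1)), hz=hz, valid=valid)
        att = gp.screen_attendance(rec, gp.FrameTimeline(n_frames, fps))
        assert att.fraction == pytest.approx(frame_mask.mean())

    def test_invariant_to_sample_order_within_frame(self):
        # attendance counts frames, not samples: permuting which samples in a
        # frame are valid leaves the fraction unchanged
        hz, n_frames = 300.0, 10
        n = int(n_frames / 25.0 * hz)
        valid = np.zeros(n, bool)
        valid[::12] = True      # one valid sample per frame, first slot
        rec1 = make_stream(np.tile([9.0, 9.0], (n, 1)), hz=hz, valid=valid)
        valid2 = np.zeros(n, bool)
        valid2[11::12] = True   # last slot instead
        rec2 = make_stream(np.tile([9.0, 9.0], (n, 1)), hz=hz, valid=valid2)
        tl = gp.FrameTimeline(n_frames, 25.0)
        assert (gp.screen_attendance(rec1, tl).fraction
                == gp.screen_attendance(rec2, tl).fraction)


# ---------------------------------------------------------------------------
# fixation -> frame mapping

class TestFrameMapping:
    def test_single_spanning_fixation_covers_all(self):
        tl = gp.FrameTimeline(n_frames=20, fps=25.0)
        fix = gp.Fixation(onset=0.0, offset=tl.duration, centroid_xy=(5.0, 6.0))
        pts = gp.map_fixations_to_frames([fix], tl)
        assert np.allclose(pts, [5.0, 6.0])

    def test_saccade_interval_missing(self):
        tl = gp.FrameTimeline(n_frames=10, fps=25.0)
        fixes = [gp.Fixation(0.00, 0.10, (1.0, 1.0)),
                 gp.Fixation(0.30, 0.40, (2.0, 2.0))]
        pts = gp.map_fixations_to_frames(fixes, tl)
        # frames whose midpoint falls in the 0.10-0.30 saccade are missing
        assert np.isnan(pts[4]).all()
        assert np.isfinite(pts[0]).all() and np.isfinite(pts[8]).all()

    def test_matches_interval_intersection_oracle(self):
        tl = gp.FrameTimeline(n_frames=30, fps=25.0)
        fixes = [gp.Fixation(0.02, 0.31, (10.0, 11.0)),
                 gp.Fixation(0.40, 0.55, (20.0, 21.0)),
                 gp.Fixation(0.90, 1.18, (30.0, 31.0))]
        got = gp.map_fixations_to_frames(fixes, tl)
        for f in range(tl.n_frames):
            mid = (f + 0.5) / tl.fps
            exp = None
            for fix in fixes:
                if fix.onset <= mid <= fix.offset:
                    exp = fix.centroid_xy
            if exp is None:
                assert np.isnan(got[f]).all()
            else:
                assert tuple(got[f]) == exp
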