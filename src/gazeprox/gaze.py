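"""Gaze recording I/O, pixel/degree geometry, I-VT fixation filtering and frame mapping.

A recording is a stream of binocular gaze samples acquired while a participant
freely views a dynamic stimulus on a fixed screen.  This module reads delimited
sample exports, converts pixel displacements to visual angle with a planar
screen model, extracts fixations with a velocity-threshold (I-VT) filter,
computes screen attendance for quality control, and assigns each video frame
the fixation active at its temporal midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "TOBII_TX300",
    "FrameTimeline",
    "GazeRecording",
    "Fixation",
    "Attendance",
    "GazeFormatError",
    "GazeDataError",
    "load_gaze_recording",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "angular_distance_deg",
    "ivt_fixation_filter",
    "screen_attendance",
    "map_fixations_to_frames",
    "write_fixations",
]

#: Sampling rates this package expects from supported eye trackers (Hz).
SUPPORTED_SAMPLING_HZ = (300.0, 60.0)


class GazeFormatError(ValueError):
    """Raised when a gaze file does not match the declared column layout."""


class GazeDataError(ValueError):
    """Raised when gaze data violate a structural invariant (e.g. time order)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical/pixel geometry of the presentation screen.

    The screen subtends ``width_deg`` x ``height_deg`` of visual angle at the
    nominal viewing distance; pixel-to-degree conversion back-solves the
    physical panel size from those angles and applies planar trigonometry.
    """

    width_px: int
    height_px: int
    width_deg: float
    height_deg: float
    viewing_distance_cm: float
    refresh_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_deg", "height_deg",
                     "viewing_distance_cm", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def width_cm(self) -> float:
        return 2.0 * self.viewing_distance_cm * np.tan(np.radians(self.width_deg / 2.0))

    @property
    def height_cm(self) -> float:
        return 2.0 * self.viewing_distance_cm * np.tan(np.radians(self.height_deg / 2.0))

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px


#: 1920x1200 panel subtending 45deg53' x 29deg38' at 60 cm, 60 Hz refresh.
TOBII_TX300 = ScreenGeometry(
    width_px=1920,
    height_px=1200,
    width_deg=45.0 + 53.0 / 60.0,
    height_deg=29.0 + 38.0 / 60.0,
    viewing_distance_cm=60.0,
    refresh_hz=60.0,
)


@dataclass(frozen=True)
class FrameTimeline:
    """Uniform video frame timeline: ``n_frames`` frames at ``fps`` frames/s."""

    n_frames: int
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.fps <= 0:
            raise ValueError("FrameTimeline requires n_frames >= 1 and fps > 0")

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def frame_starts(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def frame_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) / self.fps

    def frame_of_time(self, t) -> np.ndarray:
        """Index of the frame whose [start, end) interval contains each time."""
        idx = np.floor(np.asarray(t, dtype=float) * self.fps).astype(int)
        return np.clip(idx, 0, self.n_frames - 1)


#: Canonical delimited dialect: tab-separated with these columns.
CANONICAL_COLUMNS = {
    "t": "t",
    "left_x": "left_x",
    "left_y": "left_y",
    "right_x": "right_x",
    "right_y": "right_y",
    "left_valid": "left_valid",
    "right_valid": "right_valid",
}

_SAMPLE_FIELDS = ["t", "left_x", "left_y", "right_x", "right_y",
                  "left_valid", "right_valid"]


@dataclass
class GazeRecording:
    """One subject/visit gaze stream plus metadata.

    ``samples`` holds one row per sample with columns ``t`` (seconds from
    stimulus onset), per-eye pixel coordinates and per-eye validity flags.
    Validity combines the tracker flag with an on-screen bounds check;
    off-screen coordinates are retained but flagged invalid.
    """

    subject_id: str
    group: str
    age_years: float
    sampling_hz: float
    samples: pd.DataFrame
    geometry: ScreenGeometry = TOBII_TX300

    def __post_init__(self) -> None:
        missing = [c for c in _SAMPLE_FIELDS if c not in self.samples.columns]
        if missing:
            raise GazeFormatError(f"sample table missing columns: {missing}")
        t = self.samples["t"].to_numpy(dtype=float)
        if len(t) and t[0] < 0:
            raise GazeDataError("timestamps must be nonnegative")
        if np.any(np.diff(t) < 0):
            raise GazeDataError("timestamps must be monotone nondecreasing")
        if self.sampling_hz not in SUPPORTED_SAMPLING_HZ:
            warnings.warn(
                f"sampling_hz={self.sampling_hz} outside the supported set "
                f"{SUPPORTED_SAMPLING_HZ}", stacklevel=2)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        t = self.samples["t"].to_numpy(dtype=float)
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def binocular_valid(self) -> np.ndarray:
        """Boolean mask: both eyes valid (used for screen attendance)."""
        s = self.samples
        return (s["left_valid"].to_numpy(bool) & s["right_valid"].to_numpy(bool))

    def midpoint_trace(self) -> np.ndarray:
        """(n, 2) binocular gaze trace in pixels.

        The trace is the midpoint of the valid eyes: both-eye samples use the
        average, monocular samples fall back to the single valid eye, fully
        invalid samples are NaN.
        """
        s = self.samples
        lx = s["left_x"].to_numpy(float)
        ly = s["left_y"].to_numpy(float)
        rx = s["right_x"].to_numpy(float)
        ry = s["right_y"].to_numpy(float)
        lv = s["left_valid"].to_numpy(bool)
        rv = s["right_valid"].to_numpy(bool)
        x = np.full(len(s), np.nan)
        y = np.full(len(s), np.nan)
        both = lv & rv
        x[both] = 0.5 * (lx[both] + rx[both])
        y[both] = 0.5 * (ly[both] + ry[both])
        only_l = lv & ~rv
        x[only_l], y[only_l] = lx[only_l], ly[only_l]
        only_r = rv & ~lv
        x[only_r], y[only_r] = rx[only_r], ry[only_r]
        return np.column_stack([x, y])


@dataclass(frozen=True)
class Fixation:
    """A fixation event from the I-VT filter.

    ``preceding_saccade_amplitude`` is the visual-angle distance (degrees)
    from the previous fixation's centroid; ``None`` for the first fixation.
    """

    onset: float
    offset: float
    centroid_xy: tuple
    n_samples: int = 0
    preceding_saccade_amplitude: float | None = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def duration_ms(self) -> float:
        return 1e3 * self.duration


@dataclass(frozen=True)
class Attendance:
    """Screen-attendance QC result."""

    fraction: float
    included: bool
    n_frames: int
    n_frames_attended: int


def _on_screen(x: np.ndarray, y: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    return ((x >= 0) & (x < geometry.width_px) & (y >= 0) & (y < geometry.height_px))


def load_gaze_recording(
    path,
    geometry: ScreenGeometry = TOBII_TX300,
    *,
    subject_id: str = "unknown",
    group: str = "test",
    age_years: float = float("nan"),
    sampling_hz: float = 300.0,
    column_map: dict | None = None,
    delimiter: str | None = None,
) -> GazeRecording:
    """Read a delimited gaze export into a validated :class:`GazeRecording`.

    Parameters
    ----------
    path : path-like
        Tab- or comma-delimited text file with one sample per row.
    column_map : dict, optional
        Mapping from canonical field names (``t``, ``left_x`` ...) to the
        file's column names.  Defaults to the canonical dialect.
    delimiter : str, optional
        Field delimiter; sniffed from the header line when omitted.
    """
    cmap = dict(CANONICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=delimiter)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing columns {missing}")
    df = pd.DataFrame({k: raw[v] for k, v in cmap.items()})
    for eye in ("left", "right"):
        x = df[f"{eye}_x"].to_numpy(float)
        y = df[f"{eye}_y"].to_numpy(float)
        flag = df[f"{eye}_valid"].astype(bool).to_numpy()
        finite = np.isfinite(x) & np.isfinite(y)
        ok = np.zeros(len(df), bool)
        ok[finite] = _on_screen(x[finite], y[finite], geometry)
        df[f"{eye}_valid"] = flag & ok
    return GazeRecording(
        subject_id=subject_id, group=group, age_years=age_years,
        sampling_hz=sampling_hz, samples=df, geometry=geometry)


def pixels_to_degrees(displacement_px, geometry: ScreenGeometry, axis: str = "x"):
    """Visual angle (degrees) subtended by a pixel displacement.

    Scalars are treated as a displacement along ``axis``; shape ``(..., 2)``
    arrays as (dx, dy) vectors whose angular magnitude is returned.  The
    conversion is planar: the displacement is mapped to centimetres on the
    panel and the full chord angle ``2*atan(d / 2L)`` is taken at viewing
    distance ``L``.  Sign is preserved for scalar displacements.
    """
    if geometry.viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    d = np.asarray(displacement_px, dtype=float)
    if d.ndim >= 1 and d.shape[-1] == 2 and axis in ("xy", "vec"):
        dx_cm = d[..., 0] * geometry.cm_per_px_x
        dy_cm = d[..., 1] * geometry.cm_per_px_y
        d_cm = np.hypot(dx_cm, dy_cm)
        signed = False
    else:
        scale = geometry.cm_per_px_x if axis == "x" else geometry.cm_per_px_y
        d_cm = d * scale
        signed = True
    ang = 2.0 * np.degrees(np.arctan(np.abs(d_cm) / (2.0 * geometry.viewing_distance_cm)))
    out = np.sign(d_cm) * ang if signed else ang
    return float(out) if np.ndim(out) == 0 else out


def degrees_to_pixels(angle_deg, geometry: ScreenGeometry, axis: str = "x"):
    """Inverse of :func:`pixels_to_degrees` for a displacement along one axis."""
    a = np.asarray(angle_deg, dtype=float)
    d_cm = 2.0 * geometry.viewing_distance_cm * np.tan(np.radians(np.abs(a) / 2.0))
    scale = geometry.cm_per_px_x if axis == "x" else geometry.cm_per_px_y
    out = np.sign(a) * d_cm / scale
    return float(out) if np.ndim(out) == 0 else out


def angular_distance_deg(p_px, q_px, geometry: ScreenGeometry):
    """Visual-angle distance (degrees) between two pixel points (broadcasting)."""
    p = np.asarray(p_px, dtype=float)
    q = np.asarray(q_px, dtype=float)
    dx_cm = (p[..., 0] - q[..., 0]) * geometry.cm_per_px_x
    dy_cm = (p[..., 1] - q[..., 1]) * geometry.cm_per_px_y
    d_cm = np.hypot(dx_cm, dy_cm)
    out = 2.0 * np.degrees(np.arctan(d_cm / (2.0 * geometry.viewing_distance_cm)))
    return float(out) if np.ndim(out) == 0 else out


def _fill_short_gaps(t: np.ndarray, xy: np.ndarray, max_gap_s: float) -> np.ndarray:
    """Linearly interpolate NaN runs no longer than ``max_gap_s``.

    Longer gaps are left as NaN and therefore break fixations downstream.
    """
    out = xy.copy()
    bad = ~np.isfinite(out[:, 0]) | ~np.isfinite(out[:, 1])
    if not bad.any() or bad.all():
        return out
    idx = np.arange(len(t))
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        lo, hi = start - 1, stop  # bracketing valid samples
        if lo < 0 or hi >= len(t):
            continue
        if t[hi] - t[lo] > max_gap_s:
            continue
        seg = idx[start:stop]
        for k in (0, 1):
            out[seg, k] = np.interp(t[seg], [t[lo], t[hi]], [xy[lo, k], xy[hi, k]])
    return out


def sample_velocities(
    recording: GazeRecording,
    velocity_window_ms: float = 20.0,
    merge_max_gap_ms: float = 75.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Angular velocity (deg/s) of the gap-filled binocular trace.

    Velocity at sample i is the visual-angle distance between the samples at
    t_i +/- half the velocity window, divided by their time difference (a
    centred difference; one-sided at the stream edges).  Returns the velocity
    array and the gap-filled (n, 2) trace.
    """
    t = recording.samples["t"].to_numpy(float)
    xy = _fill_short_gaps(t, recording.midpoint_trace(), merge_max_gap_ms / 1e3)
    n = len(t)
    v = np.full(n, np.nan)
    if n < 2:
        return v, xy
    half = max(1, int(round(recording.sampling_hz * velocity_window_ms / 2e3)))
    lo = np.clip(np.arange(n) - half, 0, n - 1)
    hi = np.clip(np.arange(n) + half, 0, n - 1)
    dt = t[hi] - t[lo]
    ok = (dt > 0) & np.isfinite(xy[lo]).all(axis=1) & np.isfinite(xy[hi]).all(axis=1)
    ang = angular_distance_deg(xy[hi[ok]], xy[lo[ok]], recording.geometry)
    v[ok] = np.asarray(ang) / dt[ok]
    return v, xy


def ivt_fixation_filter(
    recording: GazeRecording,
    velocity_threshold: float = 30.0,
    velocity_window_ms: float = 20.0,
    merge_max_gap_ms: float = 75.0,
    merge_max_angle_deg: float = 0.5,
    min_duration_ms: float | None = None,
) -> list[Fixation]:
    """I-VT fixation filter.

    Samples whose angular velocity stays below ``velocity_threshold`` (deg/s)
    are grouped into fixations; adjacent fixations closer than
    ``merge_max_gap_ms`` in time AND ``merge_max_angle_deg`` in angle are
    merged.  Tracking gaps no longer than the merge gap are interpolated;
    longer gaps break fixations.  No minimum-duration discard is applied
    unless ``min_duration_ms`` is given.
    """
    geometry = recording.geometry
    v, xy = sample_velocities(recording, velocity_window_ms, merge_max_gap_ms)
    t = recording.samples["t"].to_numpy(float)
    is_fix = np.isfinite(v) & (v < velocity_threshold) & np.isfinite(xy).all(axis=1)
    if not is_fix.any():
        warnings.warn("no fixation samples found (all-invalid or all-saccade "
                      "recording); returning empty list", stacklevel=2)
        return []

    fixations: list[Fixation] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], is_fix.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < 2:
            continue  # a single sample has zero duration
        seg = xy[start:stop]
        fixations.append(Fixation(
            onset=float(t[start]), offset=float(t[stop - 1]),
            centroid_xy=(float(seg[:, 0].mean()), float(seg[:, 1].mean())),
            n_samples=stop - start))

    # merge pass: gap <= 75 ms AND centroid separation <= 0.5 deg
    merged: list[Fixation] = []
    for fix in fixations:
        if merged:
            prev = merged[-1]
            gap = fix.onset - prev.offset
            sep = angular_distance_deg(prev.centroid_xy, fix.centroid_xy, geometry)
            if gap <= merge_max_gap_ms / 1e3 and sep <= merge_max_angle_deg:
                n = prev.n_samples + fix.n_samples
                cx = (prev.centroid_xy[0] * prev.n_samples
                      + fix.centroid_xy[0] * fix.n_samples) / n
                cy = (prev.centroid_xy[1] * prev.n_samples
                      + fix.centroid_xy[1] * fix.n_samples) / n
                merged[-1] = Fixation(onset=prev.onset, offset=fix.offset,
                                      centroid_xy=(cx, cy), n_samples=n)
                continue
        merged.append(fix)

    if min_duration_ms is not None:
        merged = [f for f in merged if f.duration_ms >= min_duration_ms]

    out: list[Fixation] = []
    for i, fix in enumerate(merged):
        amp = None
        if i > 0:
            amp = float(angular_distance_deg(
                merged[i - 1].centroid_xy, fix.centroid_xy, geometry))
        out.append(Fixation(onset=fix.onset, offset=fix.offset,
                            centroid_xy=fix.centroid_xy, n_samples=fix.n_samples,
                            preceding_saccade_amplitude=amp))
    return out


def screen_attendance(
    recording: GazeRecording,
    timeline: FrameTimeline,
    threshold: float = 0.65,
) -> Attendance:
    """Fraction of video frames with at least one binocular-valid sample.

    Recordings attending fewer than ``threshold`` (default 65%) of frames are
    flagged for exclusion.
    """
    t = recording.samples["t"].to_numpy(float)
    valid = recording.binocular_valid()
    covered = np.zeros(timeline.n_frames, bool)
    in_video = (t >= 0) & (t < timeline.duration)
    sel = valid & in_video
    if sel.any():
        covered[np.unique(timeline.frame_of_time(t[sel]))] = True
    frac = float(covered.mean())
    return Attendance(fraction=frac, included=frac >= threshold,
                      n_frames=timeline.n_frames,
                      n_frames_attended=int(covered.sum()))


def map_fixations_to_frames(
    fixations: Sequence[Fixation],
    timeline: FrameTimeline,
) -> np.ndarray:
    """Per-frame gaze point: centroid of the fixation active at each frame's
    temporal midpoint; NaN where no fixation overlaps (saccades, blinks,
    off-screen moments are omitted from all downstream calculations).

    Returns an ``(n_frames, 2)`` float array.
    """
    out = np.full((timeline.n_frames, 2), np.nan)
    if not fixations:
        return out
    mids = timeline.frame_midpoints()
    onsets = np.array([f.onset for f in fixations])
    offsets = np.array([f.offset for f in fixations])
    cents = np.array([f.centroid_xy for f in fixations])
    # fixations are time-ordered and non-overlapping
    idx = np.searchsorted(onsets, mids, side="right") - 1
    ok = idx >= 0
    ok[ok] &= mids[ok] <= offsets[idx[ok]]
    out[ok] = cents[idx[ok]]
    return out


def write_fixations(fixations: Sequence[Fixation], path, delimiter: str = "\t") -> None:
    """Write fixations as delimited text (onset, offset, duration_ms, x, y,
    preceding_saccade_deg)."""
    rows = [{
        "onset": f.onset, "offset": f.offset, "duration_ms": f.duration_ms,
        "x": f.centroid_xy[0], "y": f.centroid_xy[1],
        "preceding_saccade_deg": (np.nan if f.preceding_saccade_amplitude is None
                                  else f.preceding_saccade_amplitude),
    } for f in fixations]
    pd.DataFrame(rows, columns=["onset", "offset", "duration_ms", "x", "y",
                                "preceding_saccade_deg"]).to_csv(
        path, sep=delimiter, index=False)
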