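"""Proximity Index: frame-wise closeness of a gaze stream to a referent model.

For each frame the referent density surface is quantized into 100 linearly
spaced isoline levels.  A gaze coordinate scores k/100 where k is the highest
level whose isoline still contains it (density at the point >= level k), and
0 when it lies outside the lowest isoline.  A gaze point at the surface mode
therefore scores 1; a point whose density is half the frame maximum scores
0.50.  The subject-level summary is the mean over all scoreable frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze import (FrameTimeline, GazeRecording, ivt_fixation_filter,
                   map_fixations_to_frames, screen_attendance)
from .reference import (ContourLevels, DensitySurface, ReferenceModel,
                        build_reference, frame_points_from_recordings)

__all__ = ["PIResult", "proximity_index_frame", "proximity_index_subject",
           "loo_proximity"]

#: Relative slack when comparing density to a level, so that a point whose
#: density is analytically equal to a level (e.g. exactly half the maximum)
#: counts as inside despite floating-point rounding.
_LEVEL_RTOL = 1e-9


@dataclass
class PIResult:
    """Per-frame Proximity Index of one recording plus its summary.

    ``per_frame_pi`` has one entry per video frame; NaN marks frames without
    a fixation gaze point or without a usable reference.  Non-missing values
    lie on the grid {0, 0.01, ..., 1.00}.
    """

    subject_id: str
    per_frame_pi: np.ndarray

    @property
    def mean_pi(self) -> float:
        vals = self.per_frame_pi[np.isfinite(self.per_frame_pi)]
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def n_frames_scored(self) -> int:
        return int(np.isfinite(self.per_frame_pi).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-frame table (frame, pi)."""
        return pd.DataFrame({"subject_id": self.subject_id,
                             "frame": np.arange(len(self.per_frame_pi)),
                             "pi": self.per_frame_pi})


def proximity_index_frame(
    gaze_xy,
    density: DensitySurface,
    levels: ContourLevels,
) -> float:
    """Proximity Index of one gaze coordinate on one frame.

    PI = k / n_levels with k the highest level index whose threshold the
    interpolated density at the gaze point still meets; 0 below the lowest
    level.  Ties (density exactly at a level) count as inside.
    """
    x, y = float(gaze_xy[0]), float(gaze_xy[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        return float("nan")
    f = density.value_at(x, y)
    n = levels.n_levels
    # highest k with f >= l_k; the relative slack makes analytic ties
    # (f exactly on a level) land inside.
    k = int(np.count_nonzero(f >= np.asarray(levels.levels) * (1 - _LEVEL_RTOL)))
    return min(k, n) / n


def proximity_index_subject(
    recording: GazeRecording,
    reference: ReferenceModel,
    check_attendance: bool = True,
    attendance_threshold: float = 0.65,
    frame_points: np.ndarray | None = None,
    **ivt_kwargs,
) -> PIResult:
    """Frame-wise and mean Proximity Index of a recording against a reference.

    The recording is fixation-filtered, each frame gets the centroid of the
    fixation active at its midpoint, and each on-screen gaze point is scored
    against that frame's referent surface.  Frames with missing gaze or an
    unusable reference are excluded from the mean (no imputation).

    ``check_attendance=False`` overrides the 65% screen-attendance QC gate.
    """
    timeline = reference.timeline
    if check_attendance:
        att = screen_attendance(recording, timeline,
                                threshold=attendance_threshold)
        if not att.included:
            raise ValueError(
                f"recording {recording.subject_id!r} fails attendance QC "
                f"({att.fraction:.1%} < {attendance_threshold:.0%}); pass "
                "check_attendance=False to override")
    if frame_points is None:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixes = ivt_fixation_filter(recording, **ivt_kwargs)
        frame_points = map_fixations_to_frames(fixes, timeline)

    pi = np.full(timeline.n_frames, np.nan)
    for f in range(timeline.n_frames):
        if not reference.usable[f]:
            continue
        gx, gy = frame_points[f]
        if not (np.isfinite(gx) and np.isfinite(gy)):
            continue
        pi[f] = proximity_index_frame((gx, gy), reference.surfaces[f],
                                      reference.levels[f])
    if not np.isfinite(pi).any():
        raise ValueError(
            f"recording {recording.subject_id!r} has no scoreable frames")
    return PIResult(subject_id=recording.subject_id, per_frame_pi=pi)


def loo_proximity(
    reference_group,
    timeline: FrameTimeline,
    grid_spec=None,
    min_points_per_frame: int = 10,
    frame_points: np.ndarray | None = None,
) -> list[PIResult]:
    """Leave-one-out Proximity Index for every member of a reference group.

    Each member is scored against a reference rebuilt from the remaining
    members only, so reference members receive scores comparable to outside
    subjects.
    """
    group = list(reference_group)
    if len(group) < 3:
        raise ValueError("leave-one-out needs a group of at least 3")
    if frame_points is None:
        frame_points = frame_points_from_recordings(group, timeline)
    results = []
    idx = np.arange(len(group))
    for i in range(len(group)):
        rest = idx[idx != i]
        ref = build_reference([group[j] for j in rest], timeline,
                              grid_spec=grid_spec,
                              min_points_per_frame=min_points_per_frame,
                              frame_points=frame_points[rest])
        results.append(proximity_index_subject(
            group[i], ref, check_attendance=False,
            frame_points=frame_points[i]))
    return results
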