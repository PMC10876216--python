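"""Per-frame scene covariate timelines.

Builds the frame-aligned covariates used to relate stimulus content to gaze
divergence: visual complexity (Canny edge-pixel count, a clutter proxy),
social complexity and speech codes rasterized from manual annotation CSVs,
and frame-switch / moving-background indicator vectors.  Manual annotations
remain authoritative for cuts; an automatic hard-cut detector is provided as
plumbing for synthetic material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.morphology import thin

from .gaze import FrameTimeline

__all__ = ["FeatureTimeline", "edge_complexity", "load_annotations",
           "detect_frame_switch", "video_edge_complexity"]

#: Annotation labels carried on exclusive channels (overlap is an error).
_SPEECH_LABELS = ("monologue", "directed_speech")


@dataclass
class FeatureTimeline:
    """Frame-aligned scene covariates.

    All vectors have one entry per video frame.  ``social_complexity`` is the
    number of visible animate characters (0-3); binary channels are 0/1.
    """

    timeline: FrameTimeline
    visual_complexity: np.ndarray | None = None
    social_complexity: np.ndarray | None = None
    monologue: np.ndarray | None = None
    directed_speech: np.ndarray | None = None
    frame_switch: np.ndarray | None = None
    moving_background: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.timeline.n_frames
        for name in ("visual_complexity", "social_complexity", "monologue",
                     "directed_speech", "frame_switch", "moving_background"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length {len(v)} != n_frames {n}")
        if self.social_complexity is not None:
            sc = np.asarray(self.social_complexity)
            if not np.isin(sc, [0, 1, 2, 3]).all():
                raise ValueError("social_complexity must lie in {0,1,2,3}")

    def to_frame(self) -> pd.DataFrame:
        """Single delimited-ready table, one row per frame."""
        data = {"frame": np.arange(self.timeline.n_frames)}
        for name in ("visual_complexity", "social_complexity", "monologue",
                     "directed_speech", "frame_switch", "moving_background"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


def _auto_canny_thresholds(gray: np.ndarray) -> tuple[float, float]:
    # median-based automatic double threshold (0.67x / 1.33x the median)
    med = float(np.median(gray))
    return max(0.0, 0.67 * med), min(1.0, 1.33 * med) or 0.2


def edge_complexity(
    frame: np.ndarray,
    sigma: float = 1.0,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
) -> int:
    """Visual complexity of one frame: its Canny edge-pixel count.

    Edges are found as local maxima of the Gaussian-derivative intensity
    gradient with double-threshold hysteresis.  Thresholds default to a
    median-based automatic choice; pass explicit values for fixed thresholds.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty image")
    gray = rgb2gray(frame) if frame.ndim == 3 else frame.astype(float)
    if gray.max() > 1.0:
        gray = gray / 255.0
    if low_threshold is None or high_threshold is None:
        lo, hi = _auto_canny_thresholds(gray)
        low_threshold = lo if low_threshold is None else low_threshold
        high_threshold = hi if high_threshold is None else high_threshold
    edges = canny(gray, sigma=sigma, low_threshold=low_threshold,
                  high_threshold=high_threshold)
    # edge *length*: thin to one-pixel curves (nonmax suppression keeps both
    # pixels of a tied gradient maximum on perfectly symmetric steps)
    return int(thin(edges).sum())


def video_edge_complexity(frames: np.ndarray, **kwargs) -> np.ndarray:
    """Per-frame :func:`edge_complexity` over an image stack."""
    return np.array([edge_complexity(f, **kwargs) for f in frames])


def load_annotations(path, timeline: FrameTimeline) -> FeatureTimeline:
    """Rasterize a behavioral-observation annotation CSV onto the frame grid.

    Expected dialect: columns ``label,onset_s,offset_s`` with one event per
    row.  Interval events (``monologue``, ``directed_speech``,
    ``moving_background``, ``social_complexity:k``) mark every frame whose
    midpoint falls inside [onset, offset).  ``frame_switch`` is a point
    event: the first frame starting at or after the cut instant is coded 1.

    Speech labels are mutually exclusive, and overlapping contradictory
    social-complexity codes raise a validation error.
    """
    df = pd.read_csv(path)
    required = {"label", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file needs columns {sorted(required)}")

    n = timeline.n_frames
    mids = timeline.frame_midpoints()
    starts = timeline.frame_starts()
    social = np.zeros(n, int)
    social_set = np.zeros(n, bool)
    mono = np.zeros(n, int)
    directed = np.zeros(n, int)
    switch = np.zeros(n, int)
    moving = np.zeros(n, int)

    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        onset = float(row["onset_s"])
        offset = float(row["offset_s"])
        if label == "frame_switch":
            idx = int(np.searchsorted(starts, onset - 1e-9))
            if 0 <= idx < n:
                switch[idx] = 1
            continue
        mask = (mids >= onset) & (mids < offset)
        if label.startswith("social_complexity"):
            value = int(label.split(":", 1)[1])
            if value not in (0, 1, 2, 3):
                raise ValueError(f"social complexity {value} outside 0-3")
            clash = mask & social_set & (social != value)
            if clash.any():
                raise ValueError(
                    "overlapping contradictory social_complexity codes at "
                    f"frames {np.flatnonzero(clash)[:5].tolist()}")
            social[mask] = value
            social_set |= mask
        elif label == "monologue":
            if (mask & directed.astype(bool)).any():
                raise ValueError("monologue overlaps directed_speech")
            mono[mask] = 1
        elif label == "directed_speech":
            if (mask & mono.astype(bool)).any():
                raise ValueError("directed_speech overlaps monologue")
            directed[mask] = 1
        elif label == "moving_background":
            moving[mask] = 1
        else:
            raise ValueError(f"unknown annotation label {label!r}")

    return FeatureTimeline(timeline=timeline, social_complexity=social,
                           monologue=mono, directed_speech=directed,
                           frame_switch=switch, moving_background=moving)


def detect_frame_switch(frames: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Automatic hard-cut detector (plumbing; manual annotations are
    authoritative).

    A frame is flagged 1 when its mean absolute intensity difference to the
    previous frame exceeds ``threshold`` (intensities in [0, 1]).  The first
    frame is never a switch.
    """
    frames = np.asarray(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    gray = np.stack([rgb2gray(f) if f.ndim == 3 else f.astype(float)
                     for f in frames])
    if gray.max() > 1.0:
        gray = gray / 255.0
    diff = np.abs(np.diff(gray, axis=0)).mean(axis=(1, 2))
    out = np.zeros(len(frames), int)
    out[1:] = (diff > threshold).astype(int)
    return out
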