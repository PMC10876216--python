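"""Referent gaze distributions: adaptive KDE surfaces and 100-level isolines.

The referent ("reference") visual exploration of a group is summarized frame
by frame as a probability density of the group's gaze coordinates, estimated
with a Gaussian kernel whose bandwidth adapts to the local sample density
(pilot estimate + Abramson square-root factors).  Each frame's surface is then
quantized into 100 linearly spaced isoline levels; the Proximity Index of a
gaze point is the normalized level of the highest isoline containing it (see
:mod:`gazeprox.proximity`).

Adaptive bandwidths avoid the classic failure mode of a fixed bandwidth on
gaze data: over-smoothing the mode while under-smoothing stray points in the
tails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .gaze import (FrameTimeline, GazeRecording, ScreenGeometry, TOBII_TX300,
                   ivt_fixation_filter, map_fixations_to_frames)

__all__ = [
    "GridSpec",
    "DensitySurface",
    "ContourLevels",
    "ReferenceModel",
    "adaptive_kde",
    "level_sets",
    "build_reference",
    "reference_stability",
]


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid over the screen: one cell per ``cell_size_px`` block.

    The default 4 px cell keeps the grid comfortably below fixation precision
    while the 100-level quantization of the surface dominates the resolution
    of the final score.
    """

    width_px: int = 1920
    height_px: int = 1200
    cell_size_px: float = 4.0

    @property
    def nx(self) -> int:
        return int(np.ceil(self.width_px / self.cell_size_px))

    @property
    def ny(self) -> int:
        return int(np.ceil(self.height_px / self.cell_size_px))

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates (x vector, y vector) in pixels."""
        cx = (np.arange(self.nx) + 0.5) * self.cell_size_px
        cy = (np.arange(self.ny) + 0.5) * self.cell_size_px
        return cx, cy

    @classmethod
    def for_geometry(cls, geometry: ScreenGeometry, cell_size_px: float = 4.0) -> "GridSpec":
        return cls(geometry.width_px, geometry.height_px, cell_size_px)


@dataclass
class DensitySurface:
    """A per-frame gaze density estimate on a regular screen grid.

    ``grid`` is indexed ``[iy, ix]`` (row = y, origin top-left).  Values are
    nonnegative and the discrete integral ``grid.sum() * cell_area`` is 1.
    """

    grid: np.ndarray
    cell_size_px: float
    n_points: int

    @property
    def max_density(self) -> float:
        return float(self.grid.max())

    def integral(self) -> float:
        return float(self.grid.sum() * self.cell_size_px ** 2)

    def value_at(self, x, y) -> np.ndarray:
        """Bilinearly interpolated density at pixel coordinates (x, y).

        Interpolation between cell centers removes grid-cell aliasing at
        contour boundaries; queries outside the outermost cell centers clamp
        to the border cell.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ny, nx = self.grid.shape
        gx = np.clip(x / self.cell_size_px - 0.5, 0, nx - 1)
        gy = np.clip(y / self.cell_size_px - 0.5, 0, ny - 1)
        x0 = np.clip(np.floor(gx).astype(int), 0, nx - 2) if nx > 1 else np.zeros_like(gx, int)
        y0 = np.clip(np.floor(gy).astype(int), 0, ny - 2) if ny > 1 else np.zeros_like(gy, int)
        x1 = np.minimum(x0 + 1, nx - 1)
        y1 = np.minimum(y0 + 1, ny - 1)
        fx = gx - x0
        fy = gy - y0
        g = self.grid
        val = (g[y0, x0] * (1 - fx) * (1 - fy) + g[y0, x1] * fx * (1 - fy)
               + g[y1, x0] * (1 - fx) * fy + g[y1, x1] * fx * fy)
        return val if val.ndim else float(val)

    def argmax_xy(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(int(np.argmax(self.grid)), self.grid.shape)
        return ((ix + 0.5) * self.cell_size_px, (iy + 0.5) * self.cell_size_px)


@dataclass(frozen=True)
class ContourLevels:
    """100 (by default) linearly spaced isoline thresholds of a surface.

    Level k sits at ``k * source_max / n_levels`` for k = 1..n_levels, so the
    highest level coincides with the surface maximum.
    """

    levels: np.ndarray
    source_max: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, float)
        if lv.ndim != 1 or np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be a strictly increasing vector")
        if lv[-1] > self.source_max * (1 + 1e-12):
            raise ValueError("top level exceeds the source maximum")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def level_sets(density: DensitySurface, n_levels: int = 100) -> ContourLevels:
    """Linearly spaced isoline levels ``k * max / n_levels``, k = 1..n_levels."""
    fmax = density.max_density
    if not fmax > 0:
        raise ValueError("cannot contour a flat-zero density surface")
    k = np.arange(1, n_levels + 1)
    return ContourLevels(levels=k * fmax / n_levels, source_max=fmax)


def _silverman_bandwidths(pts: np.ndarray, weights: np.ndarray,
                          min_h: float = 1.0) -> np.ndarray:
    """Per-axis pilot bandwidths, Silverman's rule for d=2: h_j = sigma_j n^(-1/6).

    ``n`` is the number of distinct coordinates (weights carry multiplicity),
    so duplicated points reweight rather than sharpen the estimate.  Bandwidths
    are floored at ``min_h`` (one grid cell) so tight clusters still put
    well-sampled mass on the evaluation grid.
    """
    n = len(pts)
    w = weights / weights.sum()
    mu = (pts * w[:, None]).sum(axis=0)
    var = ((pts - mu) ** 2 * w[:, None]).sum(axis=0)
    sigma = np.sqrt(var)
    h = sigma * n ** (-1.0 / 6.0)
    h[~(h > 0)] = min_h
    return np.maximum(h, min_h)


def _gauss2(dx: np.ndarray, dy: np.ndarray, hx, hy) -> np.ndarray:
    return np.exp(-0.5 * ((dx / hx) ** 2 + (dy / hy) ** 2)) / (2 * np.pi * hx * hy)


def adaptive_kde(
    points: np.ndarray,
    grid_spec: GridSpec,
    adaptive: bool = True,
    pilot_bandwidth: tuple[float, float] | None = None,
) -> DensitySurface:
    """Adaptive-bandwidth Gaussian KDE of gaze points on the screen grid.

    A fixed-bandwidth pilot estimate (per-axis Silverman rule) evaluated at
    the data points yields Abramson factors ``lambda_i = (f_pilot(x_i)/g)^(-1/2)``
    with ``g`` the geometric mean of the pilot densities; each point then
    contributes a Gaussian with per-axis bandwidth ``h_j * lambda_i``.  Kernels
    are truncated at the screen bounds by globally renormalizing the surface
    to integrate to 1 on the grid.

    Set ``adaptive=False`` to force all lambda factors to 1 (plain fixed-
    bandwidth KDE, used by the equivalence tests).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise ValueError("adaptive_kde requires at least one point")
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")

    uniq, inv, counts = np.unique(pts, axis=0, return_inverse=True,
                                  return_counts=True)
    w = counts.astype(float)
    h = np.asarray(pilot_bandwidth, float) if pilot_bandwidth is not None \
        else _silverman_bandwidths(uniq, w,
                                   min_h=grid_spec.cell_size_px)

    # pilot density at the data points (weighted fixed-bandwidth KDE)
    dx = uniq[:, 0][:, None] - uniq[:, 0][None, :]
    dy = uniq[:, 1][:, None] - uniq[:, 1][None, :]
    f_pilot = (_gauss2(dx, dy, h[0], h[1]) * w[None, :]).sum(axis=1) / w.sum()

    if adaptive and len(uniq) > 1:
        logg = (w * np.log(f_pilot)).sum() / w.sum()
        lam = np.exp(-0.5 * (np.log(f_pilot) - logg))
    else:
        lam = np.ones(len(uniq))

    cx, cy = grid_spec.centers()
    grid = np.zeros((grid_spec.ny, grid_spec.nx))
    gx = cx[None, :]
    gy = cy[:, None]
    for i in range(len(uniq)):
        kx = np.exp(-0.5 * ((gx - uniq[i, 0]) / (h[0] * lam[i])) ** 2)
        ky = np.exp(-0.5 * ((gy - uniq[i, 1]) / (h[1] * lam[i])) ** 2)
        grid += (w[i] / (2 * np.pi * h[0] * h[1] * lam[i] ** 2)) * (ky @ kx)
    grid /= w.sum()

    total = grid.sum() * grid_spec.cell_size_px ** 2
    if not total > 0:
        raise ValueError("degenerate density surface (zero mass on grid)")
    grid /= total
    return DensitySurface(grid=grid, cell_size_px=grid_spec.cell_size_px,
                          n_points=int(pts.shape[0]))


@dataclass
class ReferenceModel:
    """Frame-wise referent gaze model of a reference group.

    Holds, per frame, the pooled-gaze density surface and its isoline levels.
    Frames with fewer than ``min_points_per_frame`` reference gaze points are
    flagged unusable and yield missing Proximity Index values.
    """

    surfaces: list  # DensitySurface | None per frame
    levels: list    # ContourLevels | None per frame
    usable: np.ndarray
    n_points: np.ndarray
    members: list[str]
    timeline: FrameTimeline
    grid_spec: GridSpec
    geometry: ScreenGeometry = TOBII_TX300
    min_points_per_frame: int = 10

    @property
    def n_frames(self) -> int:
        return self.timeline.n_frames

    def score(self, recording, **kwargs):
        """Proximity Index of a recording against this reference
        (see :func:`gazeprox.proximity.proximity_index_subject`)."""
        from .proximity import proximity_index_subject
        return proximity_index_subject(recording, self, **kwargs)

    def save(self, directory) -> None:
        """Serialize to a directory of per-frame arrays plus a JSON manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {f"surface_{i}": s.grid
                  for i, s in enumerate(self.surfaces) if s is not None}
        np.savez(d / "surfaces.npz", **arrays)
        manifest = {
            "members": self.members,
            "usable": self.usable.astype(int).tolist(),
            "n_points": self.n_points.astype(int).tolist(),
            "n_frames": self.timeline.n_frames,
            "fps": self.timeline.fps,
            "grid": {"width_px": self.grid_spec.width_px,
                     "height_px": self.grid_spec.height_px,
                     "cell_size_px": self.grid_spec.cell_size_px},
            "min_points_per_frame": self.min_points_per_frame,
            "geometry": {"width_px": self.geometry.width_px,
                         "height_px": self.geometry.height_px,
                         "width_deg": self.geometry.width_deg,
                         "height_deg": self.geometry.height_deg,
                         "viewing_distance_cm": self.geometry.viewing_distance_cm,
                         "refresh_hz": self.geometry.refresh_hz},
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "ReferenceModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        data = np.load(d / "surfaces.npz")
        gs = GridSpec(**manifest["grid"])
        geom = ScreenGeometry(**manifest["geometry"])
        tl = FrameTimeline(n_frames=manifest["n_frames"], fps=manifest["fps"])
        usable = np.array(manifest["usable"], bool)
        n_points = np.array(manifest["n_points"], int)
        surfaces: list = [None] * tl.n_frames
        levels: list = [None] * tl.n_frames
        for i in range(tl.n_frames):
            key = f"surface_{i}"
            if key in data:
                s = DensitySurface(grid=data[key], cell_size_px=gs.cell_size_px,
                                   n_points=int(n_points[i]))
                surfaces[i] = s
                levels[i] = level_sets(s)
        return cls(surfaces=surfaces, levels=levels, usable=usable,
                   n_points=n_points, members=manifest["members"], timeline=tl,
                   grid_spec=gs, geometry=geom,
                   min_points_per_frame=manifest["min_points_per_frame"])


def frame_points_from_recordings(
    recordings: Sequence[GazeRecording],
    timeline: FrameTimeline,
    **ivt_kwargs,
) -> np.ndarray:
    """Stack of per-frame fixation gaze points, shape (n_recordings, n_frames, 2).

    Frames without an active fixation are NaN.
    """
    out = np.full((len(recordings), timeline.n_frames, 2), np.nan)
    for i, rec in enumerate(recordings):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixes = ivt_fixation_filter(rec, **ivt_kwargs)
        out[i] = map_fixations_to_frames(fixes, timeline)
    return out


def build_reference(
    group: Sequence[GazeRecording],
    timeline: FrameTimeline,
    grid_spec: GridSpec | None = None,
    min_points_per_frame: int = 10,
    n_levels: int = 100,
    frame_points: np.ndarray | None = None,
    adaptive: bool = True,
) -> ReferenceModel:
    """Fit the frame-wise referent gaze distribution of a reference group.

    For each frame, all members' fixation gaze points are pooled and an
    adaptive KDE plus its isoline levels is fitted.  Frames with fewer than
    ``min_points_per_frame`` points are flagged unusable.

    ``frame_points`` may supply precomputed per-frame gaze (as returned by
    :func:`frame_points_from_recordings`) to skip refiltering.
    """
    if len(group) < 2:
        raise ValueError("a reference group needs at least 2 recordings")
    geometry = group[0].geometry
    if grid_spec is None:
        grid_spec = GridSpec.for_geometry(geometry)
    if frame_points is None:
        frame_points = frame_points_from_recordings(group, timeline)

    n_frames = timeline.n_frames
    surfaces: list = [None] * n_frames
    levels: list = [None] * n_frames
    usable = np.zeros(n_frames, bool)
    n_points = np.zeros(n_frames, int)
    for f in range(n_frames):
        pts = frame_points[:, f, :]
        pts = pts[np.isfinite(pts).all(axis=1)]
        n_points[f] = len(pts)
        if len(pts) < min_points_per_frame:
            continue
        surf = adaptive_kde(pts, grid_spec, adaptive=adaptive)
        surfaces[f] = surf
        levels[f] = level_sets(surf, n_levels)
        usable[f] = True
    return ReferenceModel(surfaces=surfaces, levels=levels, usable=usable,
                          n_points=n_points,
                          members=[r.subject_id for r in group],
                          timeline=timeline, grid_spec=grid_spec,
                          geometry=geometry,
                          min_points_per_frame=min_points_per_frame)


def reference_stability(
    group: Sequence[GazeRecording],
    timeline: FrameTimeline,
    sizes: Sequence[int],
    n_boot: int = 20,
    seed: int | None = None,
    probes: Sequence[GazeRecording] | None = None,
    agreement_threshold: float = 0.95,
    grid_spec: GridSpec | None = None,
    min_points_per_frame: int = 10,
) -> dict:
    """Reference stability under subsampling.

    For each candidate size, ``n_boot`` random subsamples of the group define
    sub-references; agreement is the Pearson correlation, across a held-out
    probe set, between mean-PI vectors scored on the sub-reference versus the
    full-group reference.  The curve is summarized by the smallest size whose
    mean agreement reaches ``agreement_threshold``.

    When no probe set is given, the last quarter of the group (by position)
    is held out as probes and the remainder forms the subsampling pool.
    """
    from .proximity import proximity_index_subject

    group = list(group)
    if probes is None:
        n_probe = max(2, len(group) // 4)
        probes, pool = group[-n_probe:], group[:-n_probe]
    else:
        probes, pool = list(probes), group
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 2 for s in sizes):
        raise ValueError("subsample sizes must be >= 2")
    if any(s > len(pool) for s in sizes):
        raise ValueError("subsample sizes must not exceed the pool size")

    rng = np.random.default_rng(seed)
    pool_pts = frame_points_from_recordings(pool, timeline)
    probe_pts = frame_points_from_recordings(probes, timeline)

    def _scores(model: ReferenceModel) -> np.ndarray:
        out = np.empty(len(probes))
        for i, rec in enumerate(probes):
            res = proximity_index_subject(rec, model, check_attendance=False,
                                          frame_points=probe_pts[i])
            out[i] = res.mean_pi
        return out

    full = build_reference(pool, timeline, grid_spec=grid_spec,
                           min_points_per_frame=min_points_per_frame,
                           frame_points=pool_pts)
    full_scores = _scores(full)

    curve = {}
    for size in sizes:
        ags = []
        for _ in range(n_boot):
            sel = rng.choice(len(pool), size=size, replace=False)
            sub = build_reference([pool[i] for i in sel], timeline,
                                  grid_spec=grid_spec,
                                  min_points_per_frame=min(min_points_per_frame, size),
                                  frame_points=pool_pts[sel])
            sub_scores = _scores(sub)
            if np.std(sub_scores) == 0 or np.std(full_scores) == 0:
                ags.append(0.0)
            else:
                ags.append(float(np.corrcoef(sub_scores, full_scores)[0, 1]))
        curve[size] = {"mean_agreement": float(np.mean(ags)),
                       "agreements": ags}
    stable = [s for s in sizes
              if curve[s]["mean_agreement"] >= agreement_threshold]
    return {"curve": curve,
            "smallest_stable_size": (min(stable) if stable else None),
            "threshold": agreement_threshold,
            "n_probes": len(probes)}
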