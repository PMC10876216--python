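"""Bottom-up salience maps and their fixation-predictive power (ROC AUC).

A simplified multi-channel conspicuity pipeline produces per-frame maps for
five channels — intensity, color, orientation, flicker, motion — plus a full
map (their linear combination).  Channel construction is center-surround
(difference-of-Gaussians across scales) for intensity and color opponency,
Gabor energy at 0/45/90/135 deg for orientation, frame differencing for
flicker, and matched-shift residuals in four directions for motion.  The
graph-based activation/normalization of GBVS-style models is deliberately not
reproduced: externally computed map stacks can be loaded instead, since the
analysis surface is the AUC comparison, not the salience algorithm itself.

Predictive power per frame is the area under the ROC curve of map values at
fixated locations (positives) against a negative sample (default: every grid
pixel), computed with the rank (Mann-Whitney) formulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, stats
from skimage.color import rgb2gray
from skimage.filters import gabor

__all__ = ["CHANNELS", "SalienceStack", "AUCSeries", "compute_channels",
           "salience_auc", "compare_groups_auc", "load_salience_stack"]

CHANNELS = ("intensity", "orientation", "color", "flicker", "motion")

#: Center-surround Gaussian sigma pairs (pixels).
_CS_SIGMAS = ((1.0, 4.0), (2.0, 8.0), (4.0, 16.0))
_GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GABOR_FREQ = 0.15
#: Shift (pixels) of the directional motion detectors.
MOTION_SHIFT_PX = 8


@dataclass
class SalienceStack:
    """Per-frame salience maps: ``maps[channel]`` has shape (n_frames, h, w),
    min-max normalized to [0, 1] per frame; ``full`` is the channel mean
    unless explicit weights were given."""

    maps: dict
    full: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.full)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "salience.npz", full=self.full, **self.maps)
        (d / "manifest.json").write_text(json.dumps(
            {"channels": list(self.maps), "n_frames": self.n_frames,
             "shape": list(self.full.shape[1:])}))


def load_salience_stack(directory) -> SalienceStack:
    """Load a (possibly externally computed, e.g. true GBVS) map stack."""
    d = Path(directory)
    data = np.load(d / "salience.npz")
    maps = {k: data[k] for k in data.files if k != "full"}
    return SalienceStack(maps=maps, full=data["full"])


def _minmax_per_frame(stack: np.ndarray) -> np.ndarray:
    out = np.empty_like(stack, dtype=float)
    for i, m in enumerate(stack):
        lo, hi = float(m.min()), float(m.max())
        out[i] = (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m, float)
    return out


def _gray_stack(frames: np.ndarray) -> np.ndarray:
    gray = np.stack([rgb2gray(f) if f.ndim == 3 else np.asarray(f, float)
                     for f in frames])
    if gray.max() > 1.0:
        gray = gray / 255.0
    return gray


def _center_surround(img: np.ndarray) -> np.ndarray:
    acc = np.zeros_like(img)
    for sc, ss in _CS_SIGMAS:
        acc += np.abs(ndimage.gaussian_filter(img, sc)
                      - ndimage.gaussian_filter(img, ss))
    return acc


def _shift(img: np.ndarray, direction: str, d: int) -> np.ndarray:
    # content moves by d pixels in `direction`; vacated border replicates edge
    if direction == "right":
        return np.pad(img, ((0, 0), (d, 0)), mode="edge")[:, :img.shape[1]]
    if direction == "left":
        return np.pad(img, ((0, 0), (0, d)), mode="edge")[:, d:]
    if direction == "down":
        return np.pad(img, ((d, 0), (0, 0)), mode="edge")[:img.shape[0], :]
    if direction == "up":
        return np.pad(img, ((0, d), (0, 0)), mode="edge")[d:, :]
    raise ValueError(direction)


def compute_channels(
    frames: np.ndarray,
    channels=CHANNELS,
    weights: dict | None = None,
    motion_shift_px: int = MOTION_SHIFT_PX,
) -> SalienceStack:
    """Compute the five-channel salience stack of an RGB image stack.

    ``frames`` is (n, h, w, 3) (or grayscale (n, h, w)); at least two frames
    are required when flicker or motion is requested.  Each channel map is
    min-max normalized per frame and the full map is the (weighted) mean of
    the requested channels.
    """
    frames = np.asarray(frames)
    n = len(frames)
    needs_pair = {"flicker", "motion"} & set(channels)
    if n < 2 and needs_pair:
        raise ValueError(f"channels {sorted(needs_pair)} need >= 2 frames")
    gray = _gray_stack(frames)
    rgb = frames.astype(float)
    if rgb.ndim == 3:
        rgb = np.repeat(rgb[..., None], 3, axis=-1)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0

    maps: dict[str, np.ndarray] = {}
    if "intensity" in channels:
        maps["intensity"] = np.stack([_center_surround(g) for g in gray])
    if "color" in channels:
        out = []
        for f in rgb:
            r, g, b = f[..., 0], f[..., 1], f[..., 2]
            rg = r - g                      # red/green opponency
            by = b - 0.5 * (r + g)          # blue/yellow opponency
            out.append(_center_surround(rg) + _center_surround(by))
        maps["color"] = np.stack(out)
    if "orientation" in channels:
        out = []
        for g in gray:
            acc = np.zeros_like(g)
            for theta in _GABOR_THETAS:
                re, im = gabor(g, frequency=_GABOR_FREQ, theta=theta)
                acc += np.hypot(re, im)
            out.append(acc)
        maps["orientation"] = np.stack(out)
    if "flicker" in channels:
        fl = np.zeros_like(gray)
        fl[1:] = np.abs(gray[1:] - gray[:-1])  # light onset and offset
        maps["flicker"] = fl
    if "motion" in channels:
        mo = np.zeros_like(gray)
        for i in range(1, n):
            flick = np.abs(gray[i] - gray[i - 1])
            best = np.zeros_like(gray[i])
            for direction in ("up", "down", "left", "right"):
                shifted = _shift(gray[i - 1], direction, motion_shift_px)
                energy = np.maximum(flick - np.abs(gray[i] - shifted), 0.0)
                best = np.maximum(best, energy)
            mo[i] = best
        maps["motion"] = mo

    maps = {k: _minmax_per_frame(v) for k, v in maps.items()}
    if weights:
        wsum = sum(weights.get(k, 0.0) for k in maps)
        full = sum(weights.get(k, 0.0) * v for k, v in maps.items()) / wsum
    else:
        full = np.mean(list(maps.values()), axis=0)
    return SalienceStack(maps=maps, full=_minmax_per_frame(full))


def motion_direction_energy(prev: np.ndarray, cur: np.ndarray,
                            direction: str,
                            shift_px: int = MOTION_SHIFT_PX) -> np.ndarray:
    """Single-direction motion energy map (matched-shift residual)."""
    flick = np.abs(cur - prev)
    shifted = _shift(prev, direction, shift_px)
    return np.maximum(flick - np.abs(cur - shifted), 0.0)


def salience_auc(
    salience_map: np.ndarray,
    fixation_points: np.ndarray,
    negatives: np.ndarray | None = None,
) -> float:
    """ROC AUC of a salience map for a set of fixated pixel locations.

    Positives are the map values at the fixated (x, y) locations; negatives
    default to every pixel of the map (a uniform non-fixated baseline).  The
    AUC is the Mann-Whitney rank statistic with mid-rank tie handling, so a
    constant map scores 0.5 by construction.
    """
    m = np.asarray(salience_map, float)
    pts = np.atleast_2d(np.asarray(fixation_points, float))
    if pts.size == 0:
        raise ValueError("salience_auc requires at least one fixation point")
    xi = np.clip(np.round(pts[:, 0]).astype(int), 0, m.shape[1] - 1)
    yi = np.clip(np.round(pts[:, 1]).astype(int), 0, m.shape[0] - 1)
    pos = m[yi, xi]
    neg = m.ravel() if negatives is None else np.asarray(negatives, float).ravel()
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return 0.5
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class AUCSeries:
    """Per-frame AUC values of one group for one channel."""

    values: np.ndarray
    group: str
    channel: str = "full"

    def __len__(self) -> int:
        return len(self.values)


def shuffled_fixation_negatives(all_frame_points: np.ndarray,
                                frame: int, rng) -> np.ndarray:
    """Optional negative sampler: fixations drawn from other frames."""
    other = np.delete(np.arange(all_frame_points.shape[0]), frame)
    pick = rng.choice(other, size=min(len(other), 50), replace=False)
    pts = all_frame_points[pick].reshape(-1, 2)
    return pts[np.isfinite(pts).all(axis=1)]


def compare_groups_auc(series_a: AUCSeries, series_b: AUCSeries) -> dict:
    """Paired frame-wise comparison of two groups' AUC series.

    Uses the Wilcoxon signed-rank test over frames (pairing the group-mean
    AUC per frame).  The effect size is reported both as printed in the
    source convention (``r = Z/N``) and in the conventional form
    (``r = Z/sqrt(N)``); N is the number of non-tied frame pairs.
    """
    a, b = np.asarray(series_a.values, float), np.asarray(series_b.values, float)
    if a.shape != b.shape:
        raise ValueError("AUC series must cover the same frame set")
    ok = np.isfinite(a) & np.isfinite(b)
    diff = a[ok] - b[ok]
    n = int(np.count_nonzero(diff))
    if n == 0:
        return {"statistic": 0.0, "p_value": 1.0, "z": 0.0, "n": 0,
                "effect_size_z_over_n": 0.0, "effect_size_z_over_sqrt_n": 0.0}
    res = stats.wilcoxon(a[ok], b[ok], zero_method="wilcox", method="approx")
    # direction-signed normal deviate: positive when series A exceeds B
    d = diff[diff != 0]
    ranks = stats.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = float((t_plus - mu) / sd) if sd > 0 else 0.0
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "z": z,
        "n": n,
        "effect_size_z_over_n": z / n,
        "effect_size_z_over_sqrt_n": z / np.sqrt(n),
    }
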