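"""Synthetic stimuli, cohorts and phenotypes with known ground truth.

The generator emulates, at desk scale, the structure of a free-viewing study
of a short animated social scene: a scripted set of per-frame attention foci
(the "story"), a video rendering of those foci over a textured background
with hard cuts and background motion, groups of subjects whose gaze clusters
around the scripted foci with subject-specific noise and occasional
idiosyncratic foci, longitudinal age structure with yearly repeat visits, and
a phenotype matrix sharing a planted latent factor with the mean Proximity
Index.  Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze import (FrameTimeline, GazeRecording, ScreenGeometry, TOBII_TX300)

__all__ = ["SceneScript", "CohortSpec", "make_scene_script", "generate_video",
           "generate_subject_gaze", "generate_cohort_gaze",
           "generate_phenotype"]


@dataclass
class SceneScript:
    """Ground-truth script of a synthetic animated scene.

    ``foci[f]`` is a list of (x, y, weight) attention foci for frame f with
    weights summing to 1; ``cut_frames`` are hard-cut frame indices;
    ``background_velocity[f]`` is the (vx, vy) pixel/frame drift of the
    background; ``char_count[f]`` the number of animate characters (0-3);
    ``speech`` a list of (label, onset_s, offset_s) intervals.
    """

    n_frames: int
    fps: float
    screen: ScreenGeometry
    foci: list
    cut_frames: list
    background_velocity: np.ndarray
    char_count: np.ndarray
    speech: list

    @property
    def timeline(self) -> FrameTimeline:
        return FrameTimeline(n_frames=self.n_frames, fps=self.fps)

    def focus_positions(self, frame: int) -> np.ndarray:
        return np.array([(x, y) for x, y, _ in self.foci[frame]])

    def primary_focus(self, frame: int) -> tuple[float, float]:
        """Highest-weight focus of a frame (script ground truth)."""
        x, y, _ = max(self.foci[frame], key=lambda f: f[2])
        return (x, y)


def make_scene_script(
    n_frames: int = 500,
    fps: float = 25.0,
    screen: ScreenGeometry = TOBII_TX300,
    n_cuts: int = 5,
    max_foci: int = 3,
    seed: int | None = None,
) -> SceneScript:
    """Script a scene: segments between hard cuts, each with 1..max_foci
    smoothly moving weighted foci, alternating speech codes, and moving-
    background stretches."""
    rng = np.random.default_rng(seed)
    w, h = screen.width_px, screen.height_px
    margin = 0.15
    if n_cuts > 0:
        cuts = np.sort(rng.choice(np.arange(10, n_frames - 5), size=n_cuts,
                                  replace=False)).tolist()
    else:
        cuts = []
    bounds = [0] + cuts + [n_frames]

    foci: list = [None] * n_frames
    char_count = np.zeros(n_frames, int)
    bg_vel = np.zeros((n_frames, 2))
    speech = []
    for si in range(len(bounds) - 1):
        a, b = bounds[si], bounds[si + 1]
        k = int(rng.integers(1, max_foci + 1))
        starts = rng.uniform([margin * w, margin * h],
                             [(1 - margin) * w, (1 - margin) * h], size=(k, 2))
        vels = rng.uniform(-2.0, 2.0, size=(k, 2))  # px per frame
        weights = rng.dirichlet(np.ones(k) * 5)
        for f in range(a, b):
            pos = starts + vels * (f - a)
            pos[:, 0] = np.clip(pos[:, 0], 0.05 * w, 0.95 * w)
            pos[:, 1] = np.clip(pos[:, 1], 0.05 * h, 0.95 * h)
            foci[f] = [(float(p[0]), float(p[1]), float(wt))
                       for p, wt in zip(pos, weights)]
            char_count[f] = k
        if rng.random() < 0.4:  # moving-background stretch
            bg_vel[a:b] = rng.uniform(-1.5, 1.5, size=2)
        label = "monologue" if si % 2 == 0 else "directed_speech"
        speech.append((label, a / fps, b / fps))
    return SceneScript(n_frames=n_frames, fps=fps, screen=screen, foci=foci,
                       cut_frames=cuts, background_velocity=bg_vel,
                       char_count=char_count, speech=speech)


def generate_video(
    script: SceneScript,
    size: tuple[int, int] = (120, 192),
    n_blobs: int = 6,
    seed: int | None = None,
) -> np.ndarray:
    """Render the script as a small RGB uint8 image stack (n, h, w, 3).

    Each cut segment gets its own background color and blob texture (shifted
    by the scripted background velocity); bright discs mark the foci, so more
    foci mean more edges and the scripted cuts are recoverable by a
    frame-difference detector.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    sx = w / script.screen.width_px
    sy = h / script.screen.height_px
    bounds = [0] + list(script.cut_frames) + [script.n_frames]
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.zeros((script.n_frames, h, w, 3), np.uint8)
    for si in range(len(bounds) - 1):
        a, b = bounds[si], bounds[si + 1]
        base = rng.integers(30, 140, size=3)
        blobs = rng.uniform([0, 0], [w, h], size=(n_blobs, 2))
        blob_r = rng.uniform(4, 10, size=n_blobs)
        blob_col = rng.integers(60, 200, size=(n_blobs, 3))
        offset = np.zeros(2)
        for f in range(a, b):
            img = np.tile(base[None, None, :], (h, w, 1)).astype(float)
            for (bx, by), r, col in zip(blobs, blob_r, blob_col):
                px = (bx + offset[0]) % w
                py = (by + offset[1]) % h
                m = (xx - px) ** 2 + (yy - py) ** 2 <= r ** 2
                img[m] = col
            for x, y, wt in script.foci[f]:
                r = 3 + 4 * wt
                m = (xx - x * sx) ** 2 + (yy - y * sy) ** 2 <= r ** 2
                img[m] = (250, 240, 120)
            frames[f] = np.clip(img, 0, 255).astype(np.uint8)
            offset += script.background_velocity[f] * np.array([sx, sy]) * 8
    return frames


@dataclass
class CohortSpec:
    """Study-condition knobs of a synthetic gaze cohort (one group).

    ``on_script`` is the probability that a dwell targets a scripted focus
    (vs the subject's persistent idiosyncratic focus); ``noise_sd_px`` the
    isotropic gaze scatter around the target, optionally growing/shrinking
    with age via ``noise_age_slope`` (px per year relative to ``age_ref``);
    ``dropout`` the fraction of time lost to blink gaps; visits are spaced
    one year apart.
    """

    n_subjects: int = 20
    group: str = "reference"
    age_range: tuple[float, float] = (1.7, 4.5)
    visits: int = 1
    on_script: float = 0.92
    noise_sd_px: float = 90.0
    noise_age_slope: float = 0.0
    age_ref: float = 3.0
    idiosyncratic_sd_px: float = 60.0
    dropout: float = 0.08
    sampling_hz: float = 300.0
    dwell_frames: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.on_script <= 1 and 0 <= self.dropout < 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd_px <= 0:
            raise ValueError("noise_sd_px must be positive")

    def noise_sd_at(self, age: float) -> float:
        return max(1.0, self.noise_sd_px
                   + self.noise_age_slope * (age - self.age_ref))


def _truncate_to_screen(xy: np.ndarray, screen: ScreenGeometry) -> np.ndarray:
    xy[..., 0] = np.clip(xy[..., 0], 1.0, screen.width_px - 2.0)
    xy[..., 1] = np.clip(xy[..., 1], 1.0, screen.height_px - 2.0)
    return xy


def generate_subject_gaze(
    script: SceneScript,
    spec: CohortSpec,
    subject_id: str,
    age: float,
    rng: np.random.Generator,
) -> tuple[GazeRecording, dict]:
    """One recording: dwell-structured gaze around scripted or idiosyncratic
    foci, rendered as a binocular sample stream the I-VT filter can segment.

    Gaze holds still for each dwell (a fixation), jumps instantaneously at
    dwell changes (a saccade), and blink gaps mark samples invalid.
    """
    screen = script.screen
    hz = spec.sampling_hz
    n_frames = script.n_frames
    duration = n_frames / script.fps
    idio = _truncate_to_screen(
        rng.uniform([0, 0], [screen.width_px, screen.height_px]),
        screen).copy()
    sd = spec.noise_sd_at(age)

    # dwell targets per frame
    targets = np.empty((n_frames, 2))
    dwell_on_script = []
    f = 0
    while f < n_frames:
        length = max(1, int(rng.normal(spec.dwell_frames, spec.dwell_frames / 3)))
        end = min(n_frames, f + length)
        on_script = rng.random() < spec.on_script
        if on_script:
            frame_foci = script.foci[f]
            wts = np.array([wt for _, _, wt in frame_foci])
            pick = rng.choice(len(frame_foci), p=wts / wts.sum())
            cx, cy, _ = script.foci[f][pick]
            center = np.array([cx, cy])
            jitter = rng.normal(0, sd, size=2)
        else:
            center = idio
            jitter = rng.normal(0, spec.idiosyncratic_sd_px, size=2)
        point = _truncate_to_screen(center + jitter, screen)
        targets[f:end] = point
        dwell_on_script.append((f, end, bool(on_script)))
        f = end

    n_samples = int(round(duration * hz))
    t = np.arange(n_samples) / hz
    frame_idx = np.minimum((t * script.fps).astype(int), n_frames - 1)
    gaze = targets[frame_idx] + rng.normal(0, 1.0, size=(n_samples, 2))
    gaze = _truncate_to_screen(gaze, screen)

    valid = np.ones(n_samples, bool)
    if spec.dropout > 0:
        # blinks are frame-aligned blocks (~150 ms) so the dropout rate is
        # the expected fraction of unattended frames
        blink_frames = max(1, round(0.15 * script.fps))
        n_blocks = int(np.ceil(n_frames / blink_frames))
        n_blinks = int(round(spec.dropout * n_blocks))
        for block in rng.choice(n_blocks, size=n_blinks, replace=False):
            f0 = block * blink_frames
            f1 = min(n_frames, f0 + blink_frames)
            valid[(frame_idx >= f0) & (frame_idx < f1)] = False

    vergence = rng.normal(8.0, 1.0)  # interocular pixel offset
    samples = pd.DataFrame({
        "t": t,
        "left_x": gaze[:, 0] - vergence / 2,
        "left_y": gaze[:, 1],
        "right_x": gaze[:, 0] + vergence / 2,
        "right_y": gaze[:, 1],
        "left_valid": valid,
        "right_valid": valid,
    })
    rec = GazeRecording(subject_id=subject_id, group=spec.group,
                        age_years=age, sampling_hz=hz, samples=samples,
                        geometry=screen)
    truth = {"idiosyncratic_focus": idio.tolist(),
             "dwells": dwell_on_script,
             "noise_sd_px": sd,
             "dropout_mask_fraction": float(1 - valid.mean())}
    return rec, truth


def generate_cohort_gaze(
    script: SceneScript,
    spec: CohortSpec,
    seed: int | None = None,
) -> tuple[list[GazeRecording], dict]:
    """A whole group's recordings (with yearly repeat visits) + ground truth.

    Returns one recording per subject-visit; subject ``s`` at visit ``v`` has
    id ``{group}{s:03d}`` and age ``base_age + v`` years.
    """
    rng = np.random.default_rng(seed)
    recordings: list[GazeRecording] = []
    truth: dict = {"subjects": {}, "spec": spec, "seed": seed}
    for s in range(spec.n_subjects):
        sid = f"{spec.group}{s:03d}"
        base_age = rng.uniform(*spec.age_range)
        for v in range(spec.visits):
            rec, rec_truth = generate_subject_gaze(
                script, spec, sid, base_age + v, rng)
            recordings.append(rec)
            truth["subjects"].setdefault(sid, []).append(rec_truth)
    return recordings, truth


def generate_phenotype(
    mean_pi: np.ndarray,
    loading_pattern: np.ndarray | None = None,
    latent_corr: float = 0.5,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
    ages: np.ndarray | None = None,
    age_confound: float = 0.0,
    var_names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotype matrix sharing a planted latent factor with mean PI.

    The latent factor correlates with standardized mean PI at
    ``latent_corr``; variable j is ``loading_j * latent + noise`` plus an
    optional age confound, with entries knocked out at ``missing_rate``.
    Defaults emulate a 12-variable behavioral battery with signed loadings.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(mean_pi, float)
    n = len(pi)
    if loading_pattern is None:
        loading_pattern = np.array([-0.4, -0.3,          # symptom scales
                                    0.7, 0.6, 0.6, 0.65, 0.5, 0.55,  # devel.
                                    0.6, 0.55, 0.6, 0.5])            # adaptive
    L = np.asarray(loading_pattern, float)
    z_pi = (pi - pi.mean()) / pi.std() if pi.std() > 0 else np.zeros(n)
    latent = latent_corr * z_pi + np.sqrt(max(0.0, 1 - latent_corr ** 2)) \
        * rng.standard_normal(n)
    X = latent[:, None] * L[None, :] + noise_sd * rng.standard_normal((n, len(L)))
    if ages is not None and age_confound:
        a = np.asarray(ages, float)
        X += age_confound * ((a - a.mean())[:, None])
    if missing_rate > 0:
        mask = rng.random(X.shape) < missing_rate
        # keep at least one observed value per column
        for j in range(X.shape[1]):
            if mask[:, j].all():
                mask[rng.integers(n), j] = False
        X[mask] = np.nan
    names = var_names or [f"pheno_{j + 1:02d}" for j in range(len(L))]
    df = pd.DataFrame(X, columns=names)
    truth = {"latent": latent, "loadings": L, "latent_corr": latent_corr}
    return df, truth
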