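"""Group-level inference: PLS correlation, sliding age windows, dispersion.

Three pieces of machinery:

* **PLS correlation** (:class:`PLSCorrelation` / :class:`PLSCResults`):
  relates two z-scored data blocks A (n x a) and B (n x b) by singular value
  decomposition of their cross-correlation matrix ``R = B' A / (n - 1)``.
  The singular vectors (saliences) give the variable patterns that best
  explain the shared covariance; projecting each block on its own saliences
  yields latent scores ``La = A V`` and ``Lb = B U`` whose correlation per
  component summarizes the association.  Component significance is assessed
  by row permutation of B, loading stability by bootstrap resampling with
  Procrustes alignment.

* **Sliding windows** (:func:`sliding_windows`): age-ordered blocks of a
  fixed number of recordings advanced one recording at a time; windows that
  would contain two recordings of the same subject are skipped, so every
  window mixes distinct individuals.

* **Dispersion** (:func:`dispersion`, :func:`dispersion_permutation_test`):
  group gaze coherence as the mean pairwise distance between the gaze
  coordinates present on a frame, averaged over frames, with a label-
  reshuffling permutation test of the between-group difference per window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "regress_out", "impute", "PLSCorrelation", "PLSCResults", "plsc",
    "WindowSet", "sliding_windows", "pair_window_sets",
    "dispersion", "dispersion_permutation_test", "DispersionResult",
    "group_compare",
]


# ---------------------------------------------------------------------------
# covariate handling

def regress_out(X, covariate) -> np.ndarray:
    """Residualize every column of X on [1, covariate] by least squares.

    A constant covariate degenerates to intercept-only centering (warning).
    """
    X = np.asarray(X, float)
    c = np.asarray(covariate, float).ravel()
    if len(c) != X.shape[0]:
        raise ValueError("covariate length must match rows of X")
    if np.ptp(c) == 0:
        warnings.warn("constant covariate: centering columns only",
                      stacklevel=2)
        design = np.ones((len(c), 1))
    else:
        design = np.column_stack([np.ones(len(c)), c])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def impute(X, method: str = "median") -> tuple[np.ndarray, np.ndarray]:
    """Fill missing entries column-wise; returns (complete matrix, mask).

    ``method`` is ``'median'`` (default) or ``'mean'``.  Every column must
    have at least one observed value.
    """
    X = np.asarray(X, float).copy()
    mask = ~np.isfinite(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            raise ValueError(f"column {j} is entirely missing")
        fill = np.median(obs) if method == "median" else np.mean(obs)
        col[~np.isfinite(col)] = fill
    return X, mask


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        warnings.warn("constant column(s) in PLS input; set to zero",
                      stacklevel=3)
        sd = np.where(bad, 1.0, sd)
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# PLS correlation

@dataclass
class PLSCResults:
    """Fitted PLS-correlation results.

    Attributes
    ----------
    u, v : ndarray
        Column-orthonormal saliences of the B side (b x k) and A side (a x k).
    singular_values : ndarray
        Singular values of the cross-correlation matrix.
    latent_a, latent_b : ndarray
        Latent scores La = A_z V and Lb = B_z U (n x k).
    latent_correlations : ndarray
        corr(La_k, Lb_k) per component.
    perm_pvalues : ndarray or None
        Permutation p-value per component (+1-corrected, never exactly 0).
    boot_u_lo, boot_u_hi, boot_v_lo, boot_v_hi : ndarray or None
        Bootstrap 5th-95th percentile intervals for each loading.
    u_stable, v_stable : ndarray or None
        True where the bootstrap interval excludes zero.
    """

    u: np.ndarray
    v: np.ndarray
    singular_values: np.ndarray
    latent_a: np.ndarray
    latent_b: np.ndarray
    latent_correlations: np.ndarray
    n_obs: int
    perm_pvalues: np.ndarray | None = None
    n_perm: int = 0
    boot_u_lo: np.ndarray | None = None
    boot_u_hi: np.ndarray | None = None
    boot_v_lo: np.ndarray | None = None
    boot_v_hi: np.ndarray | None = None
    u_stable: np.ndarray | None = None
    v_stable: np.ndarray | None = None
    n_boot: int = 0
    a_names: list[str] | None = None
    b_names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def explained_covariance(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        return s2 / s2.sum() if s2.sum() > 0 else s2

    def summary(self) -> str:
        lines = ["PLS correlation results",
                 "=" * 55,
                 f"observations: {self.n_obs}   components: {self.n_components}"
                 f"   permutations: {self.n_perm}   bootstraps: {self.n_boot}",
                 "-" * 55,
                 f"{'comp':>4} {'sing.val':>10} {'latent r':>10} {'perm p':>10}"]
        for k in range(self.n_components):
            p = (f"{self.perm_pvalues[k]:10.4f}"
                 if self.perm_pvalues is not None else f"{'':>10}")
            lines.append(f"{k + 1:>4} {self.singular_values[k]:10.4f} "
                         f"{self.latent_correlations[k]:10.4f} {p}")
        if self.u_stable is not None:
            names = (self.b_names
                     or [f"b{j + 1}" for j in range(self.u.shape[0])])
            lines += ["-" * 55,
                      "component-1 B-side loadings (bootstrap 5th-95th pct):"]
            for j, name in enumerate(names):
                tag = "stable" if self.u_stable[j, 0] else "  --  "
                lines.append(
                    f"  {name:>12} {self.u[j, 0]:8.3f} "
                    f"[{self.boot_u_lo[j, 0]:7.3f}, {self.boot_u_hi[j, 0]:7.3f}] {tag}")
        return "\n".join(lines)

    def plot_loadings(self, component: int = 0, ax=None):
        """Bar plot of B-side loadings; unstable loadings are drawn gray."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        b = self.u[:, component]
        names = self.b_names or [f"b{j + 1}" for j in range(len(b))]
        if self.u_stable is not None:
            colors = ["tab:red" if s else "0.6"
                      for s in self.u_stable[:, component]]
        else:
            colors = ["tab:red"] * len(b)
        ax.bar(range(len(b)), b, color=colors)
        if self.boot_u_lo is not None:
            err = np.vstack([b - self.boot_u_lo[:, component],
                             self.boot_u_hi[:, component] - b])
            ax.errorbar(range(len(b)), b, yerr=np.abs(err), fmt="none",
                        ecolor="k", capsize=2, lw=1)
        ax.set_xticks(range(len(b)), names, rotation=60, ha="right")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel(f"loading (component {component + 1})")
        return ax


def _procrustes_rotation(ref: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthonormal rotation aligning ``target`` onto ``ref`` (sign/rotation
    indeterminacy of SVD factors)."""
    p, _, qt = np.linalg.svd(ref.T @ target)
    return (p @ qt).T


class PLSCorrelation:
    """PLS correlation model between two observation-aligned data blocks.

    Parameters
    ----------
    a, b : array-like (n x a), (n x b)
        The two blocks; rows are observations.  Both are z-scored internally.
    a_names, b_names : sequence of str, optional
        Variable names for summaries and plots.
    """

    def __init__(self, a, b, a_names=None, b_names=None):
        if isinstance(a, pd.DataFrame):
            a_names = a_names or list(a.columns)
            a = a.to_numpy(float)
        if isinstance(b, pd.DataFrame):
            b_names = b_names or list(b.columns)
            b = b.to_numpy(float)
        a = np.atleast_2d(np.asarray(a, float))
        b = np.atleast_2d(np.asarray(b, float))
        if a.ndim == 2 and a.shape[0] == 1:
            a = a.T
        if b.ndim == 2 and b.shape[0] == 1:
            b = b.T
        if a.shape[0] != b.shape[0]:
            raise ValueError("A and B must have the same number of rows")
        if a.shape[0] < 5:
            raise ValueError("PLS correlation needs at least 5 observations")
        self.a_raw = a
        self.b_raw = b
        self.a_names = a_names
        self.b_names = b_names

    @staticmethod
    def _decompose(a_z: np.ndarray, b_z: np.ndarray):
        n = a_z.shape[0]
        r = b_z.T @ a_z / (n - 1)
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        return r, u, s, vt.T

    def fit(self, n_perm: int = 1000, n_boot: int = 1000,
            seed: int | None = None) -> PLSCResults:
        """Decompose, then permutation-test components and bootstrap loadings.

        Permutations shuffle the rows of B only (breaking the A-B pairing
        while preserving each block's internal structure); the k-th permuted
        singular value is compared to the k-th observed one without
        re-sorting.  Bootstraps resample rows with replacement; resampled
        saliences are Procrustes-aligned (one rotation computed from the
        stacked [U; V] block) to the original before taking 5th-95th
        percentile intervals.  A loading is "stable" when its interval
        excludes zero.
        """
        rng = np.random.default_rng(seed)
        a_z, b_z = _zscore(self.a_raw), _zscore(self.b_raw)
        r, u, s, v = self._decompose(a_z, b_z)
        if not np.any(s > 1e-12):
            warnings.warn("rank-0 cross-correlation matrix; no components",
                          stacklevel=2)
        la = a_z @ v
        lb = b_z @ u
        lat = np.array([
            np.corrcoef(la[:, k], lb[:, k])[0, 1]
            if la[:, k].std() > 0 and lb[:, k].std() > 0 else 0.0
            for k in range(len(s))])

        n = a_z.shape[0]
        perm_p = None
        if n_perm:
            exceed = np.zeros(len(s))
            for _ in range(n_perm):
                b_perm = self.b_raw[rng.permutation(n)]
                _, _, s_perm, _ = self._decompose(a_z, _zscore(b_perm))
                exceed += s_perm >= s
            perm_p = (1.0 + exceed) / (n_perm + 1.0)

        boot = {}
        u_stable = v_stable = None
        if n_boot:
            us = np.empty((n_boot,) + u.shape)
            vs = np.empty((n_boot,) + v.shape)
            stacked_ref = np.vstack([u, v])
            for i in range(n_boot):
                sel = rng.integers(0, n, size=n)
                while np.ptp(sel) == 0:  # degenerate single-row resample
                    sel = rng.integers(0, n, size=n)
                _, ub, sb, vb = self._decompose(_zscore(self.a_raw[sel]),
                                                _zscore(self.b_raw[sel]))
                rot = _procrustes_rotation(stacked_ref, np.vstack([ub, vb]))
                us[i] = ub @ rot
                vs[i] = vb @ rot
            boot = {
                "boot_u_lo": np.percentile(us, 5, axis=0),
                "boot_u_hi": np.percentile(us, 95, axis=0),
                "boot_v_lo": np.percentile(vs, 5, axis=0),
                "boot_v_hi": np.percentile(vs, 95, axis=0),
            }
            u_stable = (boot["boot_u_lo"] > 0) | (boot["boot_u_hi"] < 0)
            v_stable = (boot["boot_v_lo"] > 0) | (boot["boot_v_hi"] < 0)

        return PLSCResults(
            u=u, v=v, singular_values=s, latent_a=la, latent_b=lb,
            latent_correlations=lat, n_obs=n, perm_pvalues=perm_p,
            n_perm=n_perm, u_stable=u_stable, v_stable=v_stable,
            n_boot=n_boot, a_names=self.a_names, b_names=self.b_names,
            **boot)


def plsc(a, b, n_perm: int = 1000, n_boot: int = 1000,
         seed: int | None = None, **kwargs) -> PLSCResults:
    """Convenience wrapper: ``PLSCorrelation(a, b).fit(...)``."""
    return PLSCorrelation(a, b, **kwargs).fit(n_perm=n_perm, n_boot=n_boot,
                                              seed=seed)


# ---------------------------------------------------------------------------
# sliding windows

@dataclass
class WindowSet:
    """Age-ordered sliding windows over a cohort of recordings.

    ``windows`` holds, per retained window, the integer indices (into the
    cohort table handed to :func:`sliding_windows`) of its member recordings;
    ``skipped`` logs the start positions of windows dropped because they
    contained two recordings of the same subject.
    """

    windows: list
    mean_ages: np.ndarray
    group: str
    width: int
    skipped: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def sliding_windows(cohort: pd.DataFrame, width: int = 20, step: int = 1,
                    group: str = "") -> WindowSet:
    """Build age-sorted sliding windows of ``width`` recordings.

    ``cohort`` needs columns ``subject_id`` and ``age``; the returned window
    indices refer to ``cohort``'s positional rows.  Contiguous blocks are
    advanced by ``step``; any window containing more than one recording from
    the same subject is skipped and logged, because repeat visits a year
    apart would otherwise correlate within a window.
    """
    if not {"subject_id", "age"}.issubset(cohort.columns):
        raise ValueError("cohort needs 'subject_id' and 'age' columns")
    n = len(cohort)
    if width > n:
        raise ValueError(f"window width {width} exceeds cohort size {n}")
    order = np.argsort(cohort["age"].to_numpy(), kind="stable")
    subj = cohort["subject_id"].to_numpy()[order]
    ages = cohort["age"].to_numpy(float)[order]
    windows, mean_ages, skipped = [], [], []
    for start in range(0, n - width + 1, step):
        block = slice(start, start + width)
        if len(set(subj[block])) < width:
            skipped.append(start)
            continue
        windows.append(order[block].copy())
        mean_ages.append(ages[block].mean())
    return WindowSet(windows=windows, mean_ages=np.array(mean_ages),
                     group=group, width=width, skipped=skipped)


def pair_window_sets(ws_a: WindowSet, ws_b: WindowSet) -> list[tuple[int, int]]:
    """Pair windows across two groups by window index (truncating to the
    shorter set); mean ages let callers verify age matching."""
    k = min(ws_a.n_windows, ws_b.n_windows)
    return [(i, i) for i in range(k)]


# ---------------------------------------------------------------------------
# dispersion

def dispersion(points_per_frame) -> float:
    """Mean pairwise Euclidean distance of gaze coordinates, averaged over
    frames with at least two points (pixels).

    ``points_per_frame`` is an iterable of (n_i, 2) arrays (NaN rows are
    dropped); frames with fewer than two valid points do not contribute.
    """
    per_frame = []
    for pts in points_per_frame:
        pts = np.asarray(pts, float)
        pts = pts[np.isfinite(pts).all(axis=1)]
        if len(pts) >= 2:
            per_frame.append(pdist(pts).mean())
    if not per_frame:
        raise ValueError("no frame with >= 2 points; dispersion undefined")
    return float(np.mean(per_frame))


def _window_dispersion_from_dm(dm: np.ndarray, members: np.ndarray) -> float:
    """Window dispersion from a precomputed pairwise distance tensor.

    ``dm`` is (n_rec, n_rec, n_frames) with NaN where either recording has
    no gaze on the frame; dispersion per frame averages the valid pairs
    within ``members``, then over frames with at least one valid pair.
    """
    sub = dm[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    pairs = sub[iu]                          # (n_pairs, n_frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_frame = np.nanmean(pairs, axis=0)
    per_frame = per_frame[np.isfinite(per_frame)]
    if per_frame.size == 0:
        raise ValueError("no frame with a valid pair in this window")
    return float(per_frame.mean())


def pairwise_frame_distances(frame_points: np.ndarray) -> np.ndarray:
    """(n_rec, n_rec, n_frames) Euclidean distances between recordings'
    per-frame gaze points (NaN where either is missing)."""
    diff = frame_points[:, None, :, :] - frame_points[None, :, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


@dataclass
class DispersionResult:
    """Between-group dispersion contrast for one window pair."""

    dispersion_a: float
    dispersion_b: float
    statistic: float
    p_value: float
    n_perm: int
    significant: bool


def dispersion_permutation_test(
    window_a: np.ndarray,
    window_b: np.ndarray,
    n_perm: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> DispersionResult:
    """Permutation test of the between-group dispersion difference.

    ``window_a`` / ``window_b`` are (n_rec, n_frames, 2) stacks of per-frame
    gaze points for the two windows' member recordings.  The observed
    statistic is disp(A) - disp(B); the null is built by randomly
    reassigning the pooled individuals to two groups of the original sizes
    and recomputing the statistic.  Two-sided p with the +1 correction
    (never exactly zero).
    """
    a = np.asarray(window_a, float)
    b = np.asarray(window_b, float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each window needs at least 2 recordings")
    pooled = np.concatenate([a, b], axis=0)
    dm = pairwise_frame_distances(pooled)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    disp_a = _window_dispersion_from_dm(dm, idx_a)
    disp_b = _window_dispersion_from_dm(dm, idx_b)
    obs = disp_a - disp_b

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_a + n_b)
        null[i] = (_window_dispersion_from_dm(dm, perm[:n_a])
                   - _window_dispersion_from_dm(dm, perm[n_a:]))
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    return DispersionResult(dispersion_a=disp_a, dispersion_b=disp_b,
                            statistic=obs, p_value=float(p), n_perm=n_perm,
                            significant=p <= alpha)


def windowed_dispersion_analysis(
    frame_points_a: np.ndarray, cohort_a: pd.DataFrame,
    frame_points_b: np.ndarray, cohort_b: pd.DataFrame,
    width: int = 20, n_perm: int = 100, seed: int | None = None,
) -> pd.DataFrame:
    """Full sliding-window dispersion pipeline over two cohorts.

    Builds per-group age windows, pairs them by index, and runs the
    permutation test per window pair.  Returns one row per window with both
    groups' mean ages, dispersions, the contrast and its p-value.
    """
    ws_a = sliding_windows(cohort_a, width=width, group="A")
    ws_b = sliding_windows(cohort_b, width=width, group="B")
    rng = np.random.default_rng(seed)
    rows = []
    for ia, ib in pair_window_sets(ws_a, ws_b):
        res = dispersion_permutation_test(
            frame_points_a[ws_a.windows[ia]],
            frame_points_b[ws_b.windows[ib]],
            n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rows.append({
            "window": ia,
            "mean_age_a": ws_a.mean_ages[ia],
            "mean_age_b": ws_b.mean_ages[ib],
            "dispersion_a": res.dispersion_a,
            "dispersion_b": res.dispersion_b,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple group tests

def group_compare(values_a, values_b, test: str = "t") -> tuple[float, float]:
    """Two-sample comparison: ``'t'``, ``'mann-whitney'`` or
    ``'wilcoxon-paired'``.  Returns (statistic, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "mann-whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "wilcoxon-paired":
        if np.array_equal(a, b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
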