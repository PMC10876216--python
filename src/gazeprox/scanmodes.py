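"""Focal / ambient fixation taxonomy.

Two visual exploration modes are distinguished from fixation duration and the
amplitude of the preceding saccade: *focal* fixations (long, after a short
saccade) index detailed, high-spatial-frequency processing, while *ambient*
fixations (short, after a long saccade) index rapid gist-level scanning.
A fixation is focal iff duration > 180 ms and preceding saccade < 5 deg, and
ambient iff duration < 180 ms and preceding saccade > 5 deg; everything else
(boundary equality, mixed cases, a first fixation with no preceding saccade)
is left unclassified since it satisfies neither definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze import Fixation

__all__ = ["FOCAL_DURATION_MS", "MODE_SACCADE_DEG", "ModeProfile",
           "classify_fixation", "mode_profile"]

#: Duration threshold separating focal from ambient fixations (ms).
FOCAL_DURATION_MS = 180.0
#: Preceding-saccade amplitude threshold (degrees of visual angle).
MODE_SACCADE_DEG = 5.0


@dataclass(frozen=True)
class ModeProfile:
    """Per-subject scan-mode summary; proportions are normalized by the
    overall fixation count."""

    n_fixations: int
    n_focal: int
    n_ambient: int
    n_unclassified: int
    prop_focal: float
    prop_ambient: float
    median_fixation_duration_ms: float
    median_saccade_amplitude_deg: float


def classify_fixation(fix: Fixation) -> str:
    """Label one fixation as ``'focal'``, ``'ambient'`` or ``'unclassified'``.

    Both rules use strict inequalities, so fixations at exactly 180 ms or a
    saccade of exactly 5 deg, mixed long/long or short/short cases, and
    fixations with no preceding saccade are unclassified.
    """
    amp = fix.preceding_saccade_amplitude
    if amp is None or not np.isfinite(amp):
        return "unclassified"
    dur = fix.duration_ms
    if dur > FOCAL_DURATION_MS and amp < MODE_SACCADE_DEG:
        return "focal"
    if dur < FOCAL_DURATION_MS and amp > MODE_SACCADE_DEG:
        return "ambient"
    return "unclassified"


def mode_profile(fixations: Sequence[Fixation]) -> ModeProfile:
    """Scan-mode counts, proportions and medians over a fixation sequence."""
    fixations = list(fixations)
    if not fixations:
        raise ValueError("mode_profile requires at least one fixation")
    labels = [classify_fixation(f) for f in fixations]
    n = len(fixations)
    n_focal = labels.count("focal")
    n_ambient = labels.count("ambient")
    durs = [f.duration_ms for f in fixations]
    amps = [f.preceding_saccade_amplitude for f in fixations
            if f.preceding_saccade_amplitude is not None]
    return ModeProfile(
        n_fixations=n,
        n_focal=n_focal,
        n_ambient=n_ambient,
        n_unclassified=n - n_focal - n_ambient,
        prop_focal=n_focal / n,
        prop_ambient=n_ambient / n,
        median_fixation_duration_ms=float(np.median(durs)),
        median_saccade_amplitude_deg=(float(np.median(amps)) if amps
                                      else float("nan")),
    )


def mode_profile_table(profiles: dict[str, ModeProfile]) -> pd.DataFrame:
    """Subject x profile-field table from a {subject_id: ModeProfile} map."""
    rows = [{"subject_id": sid, **vars(p)} for sid, p in profiles.items()]
    return pd.DataFrame(rows)
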