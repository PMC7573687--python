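"""The four-category cleanliness evaluation score.

A frame's mean dirty probability is mapped to an ordinal scale describing how
well the mucosa can be evaluated:

====  =========  =============================================================
code  name       perceived level of cleanliness
====  =========  =============================================================
4     Excellent  no intestinal content
3     Good       some intestinal content, not impeding evaluation
2     Fair       substantial content, allowing only partial evaluation
1     Poor       dense content impeding evaluation of the image
====  =========  =============================================================

Three calibrated thresholds ``t1 < t2 < t3`` on the mean probability separate
the categories; a mean exactly equal to a threshold falls in the category on
the dirtier side's cleaner neighbour (lower-inclusive toward dirty), i.e.
mean < t1 -> Excellent, t1 <= mean < t2 -> Good, t2 <= mean < t3 -> Fair,
mean >= t3 -> Poor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import FovMask, FrameImage, build_patch_grid, detect_fov_mask, extract_patches
from .interpolate import (
    PatchProbabilityMap,
    PixelProbabilityMap,
    interpolate_pixel_probabilities,
    mean_dirty_probability,
)

__all__ = [
    "CATEGORY_NAMES",
    "ThresholdTriple",
    "CleanlinessScore",
    "categorize",
    "categorize_array",
    "score_frame",
    "write_scores",
    "read_scores",
]

CATEGORY_NAMES = {1: "Poor", 2: "Fair", 3: "Good", 4: "Excellent"}
_NAME_TO_CODE = {v: k for k, v in CATEGORY_NAMES.items()}


@dataclass(frozen=True)
class ThresholdTriple:
    """Ordered cut-points on the mean dirty probability."""

    t_excellent_good: float
    t_good_fair: float
    t_fair_poor: float

    def __post_init__(self) -> None:
        t1, t2, t3 = self.t_excellent_good, self.t_good_fair, self.t_fair_poor
        if not (0.0 <= t1 < t2 < t3 <= 1.0):
            raise ValueError(f"thresholds must satisfy 0 <= t1 < t2 < t3 <= 1, got {(t1, t2, t3)}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t_excellent_good, self.t_good_fair, self.t_fair_poor)


@dataclass(frozen=True)
class CleanlinessScore:
    """One frame's ordinal cleanliness category (1=Poor .. 4=Excellent)."""

    category: int
    frame_id: str = ""
    video_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_NAMES:
            raise ValueError(f"category must be 1..4, got {self.category}")

    @property
    def name(self) -> str:
        return CATEGORY_NAMES[self.category]


def categorize(mean_prob: float, thresholds: ThresholdTriple) -> int:
    """Map a mean dirty probability to a category code (4=Excellent .. 1=Poor)."""
    if not 0.0 <= mean_prob <= 1.0:
        raise ValueError(f"mean probability must lie in [0, 1], got {mean_prob}")
    return int(categorize_array(np.array([mean_prob]), thresholds)[0])


def categorize_array(mean_probs: np.ndarray, thresholds: ThresholdTriple) -> np.ndarray:
    """Vectorised categorisation; returns int codes 1..4."""
    p = np.asarray(mean_probs, dtype=np.float64)
    t = np.asarray(thresholds.as_tuple())
    # category = 4 - number of thresholds at or below the mean
    return (4 - (p[..., None] >= t).sum(axis=-1)).astype(np.int64)


def score_frame(
    frame: FrameImage,
    model,
    thresholds: ThresholdTriple,
    mask: FovMask | None = None,
    intensity_threshold: int = 10,
) -> tuple[CleanlinessScore, PixelProbabilityMap]:
    """Score one frame end to end.

    Pipeline: FOV detection -> patch lattice -> normalised patches -> model
    dirty probabilities -> bilinear pixel map -> FOV mean -> category.  A pure
    function of (frame, model weights, thresholds): scoring the same frame
    twice gives the same result, so intrarater reliability of the method is 1.
    """
    if mask is None:
        mask = detect_fov_mask(frame, intensity_threshold)
    grid = build_patch_grid(mask)
    patches = extract_patches(frame, grid)
    probs = model.predict_proba(patches)[:, 1]
    pxm = interpolate_pixel_probabilities(
        PatchProbabilityMap(grid=grid, probs=probs), mask
    )
    mean = mean_dirty_probability(pxm)
    score = CleanlinessScore(
        category=categorize(mean, thresholds),
        frame_id=frame.frame_id,
        video_id=frame.video_id,
    )
    return score, pxm


_SCORE_HEADER = ["frame_id", "video_id", "mean_prob", "category"]


def write_scores(
    rows: list[tuple[str, str, float, int]], path: str | Path
) -> None:
    """Write per-frame scores as CSV ``frame_id,video_id,mean_prob,category``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCORE_HEADER)
        for frame_id, video_id, mean_prob, category in rows:
            writer.writerow([frame_id, video_id, f"{mean_prob:.6f}", category])


def read_scores(path: str | Path) -> list[tuple[str, str, float, int]]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            cat = row["category"]
            code = _NAME_TO_CODE.get(cat, None)
            if code is None:
                code = int(cat)
            out.append((row["frame_id"], row["video_id"], float(row["mean_prob"]), code))
    return out
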