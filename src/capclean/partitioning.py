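"""Image-level cross-validation folds, class balancing and train/val splits.

Patches from the same frame must never straddle a train/test boundary, so
cross-validation folds are assigned at the frame level and every patch inherits
the fold of its frame.  Class imbalance within a patch set is capped at a 10%
excess of the majority class by random undersampling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import PatchAnnotation

__all__ = [
    "FoldAssignment",
    "split_images_into_folds",
    "undersample_to_ten_percent",
    "train_val_split",
    "write_fold_manifest",
    "read_fold_manifest",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Frame-level fold assignment for k-fold cross-validation."""

    image_to_fold: dict[str, int]
    n_folds: int
    seed: int

    def test_frames(self, fold: int) -> list[str]:
        return [f for f, k in self.image_to_fold.items() if k == fold]

    def train_frames(self, fold: int) -> list[str]:
        return [f for f, k in self.image_to_fold.items() if k != fold]


def split_images_into_folds(
    frame_ids: list[str], n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Shuffle frames and deal them into ``n_folds`` folds of near-equal size.

    Fold sizes differ by at most one frame.  Deterministic for a fixed seed.
    """
    frame_ids = list(frame_ids)
    if len(frame_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} frames, got {len(frame_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(frame_ids))
    mapping = {frame_ids[j]: i % n_folds for i, j in enumerate(order)}
    return FoldAssignment(image_to_fold=mapping, n_folds=n_folds, seed=seed)


def undersample_to_ten_percent(
    patches: list[PatchAnnotation], seed: int = 0
) -> list[PatchAnnotation]:
    """Cap the majority class at a 10% excess over the minority class.

    If the majority count exceeds ``floor(1.1 * minority)``, randomly remove
    majority-class patches until it equals that bound; otherwise the input is
    returned unchanged.  The minority class is never touched.  Output order
    follows the input order.
    """
    by_label: dict[str, list[int]] = {"clean": [], "dirty": []}
    for i, p in enumerate(patches):
        by_label[p.label].append(i)
    n_clean, n_dirty = len(by_label["clean"]), len(by_label["dirty"])
    if n_clean == 0 or n_dirty == 0:
        raise ValueError("both classes must be present for undersampling")
    majority = "clean" if n_clean >= n_dirty else "dirty"
    maj_n = max(n_clean, n_dirty)
    min_n = min(n_clean, n_dirty)
    cap = int(np.floor(1.1 * min_n))
    if maj_n <= cap:
        return list(patches)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(by_label[majority]), size=cap, replace=False)
    kept_majority = {by_label[majority][i] for i in keep}
    return [
        p
        for i, p in enumerate(patches)
        if p.label != majority or i in kept_majority
    ]


def train_val_split(
    patches: list, fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Randomly split patches into train/validation with |train| = round(f*n)."""
    if len(patches) < 2:
        raise ValueError("need at least 2 patches to split")
    rng = np.random.default_rng(seed)
    n = len(patches)
    n_train = int(round(fraction * n))
    order = rng.permutation(n)
    train = [patches[i] for i in sorted(order[:n_train])]
    val = [patches[i] for i in sorted(order[n_train:])]
    return train, val


def write_fold_manifest(
    assignment: FoldAssignment, video_ids: dict[str, str], path: str | Path
) -> None:
    """Write CSV ``frame_id,video_id,fold``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_id", "video_id", "fold"])
        for frame_id, fold in assignment.image_to_fold.items():
            writer.writerow([frame_id, video_ids.get(frame_id, ""), fold])


def read_fold_manifest(path: str | Path) -> tuple[FoldAssignment, dict[str, str]]:
    mapping: dict[str, int] = {}
    video_ids: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            mapping[row["frame_id"]] = int(row["fold"])
            video_ids[row["frame_id"]] = row["video_id"]
    n_folds = max(mapping.values()) + 1 if mapping else 0
    return FoldAssignment(image_to_fold=mapping, n_folds=n_folds, seed=-1), video_ids
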