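"""Frame ingestion, field-of-view masking and the overlapping patch lattice.

Capsule-endoscopy frames show a roughly circular recording area (the field of
view, FOV) on a black background.  All downstream analysis operates on a
lattice of 64x64-pixel patches laid over the FOV with a stride of 32 pixels in
both directions, i.e. 50% overlap per axis.  A patch belongs to the lattice
only if *all* of its pixels lie inside the FOV: annotations are defined as
"completely clean" or "completely dirty", which is meaningless for patches
that include the black border.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "FrameImage",
    "FovMask",
    "PatchGrid",
    "PatchAnnotation",
    "NoRecordingAreaError",
    "load_frame",
    "detect_fov_mask",
    "load_fov_mask",
    "build_patch_grid",
    "extract_patches",
    "read_annotations",
    "write_annotations",
]

PATCH_SIZE = 64
PATCH_STRIDE = 32

LABELS = ("clean", "dirty")


class NoRecordingAreaError(ValueError):
    """Raised when a frame contains no detectable recording area."""


@dataclass(frozen=True)
class FrameImage:
    """An 8-bit RGB capsule-endoscopy frame.

    ``pixels`` has shape (H, W, 3) with values in [0, 255].  Frames of the
    reference acquisition are 576x576 but any size is accepted.
    """

    pixels: np.ndarray
    frame_id: str
    video_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixel array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class FovMask:
    """Boolean mask of the recording area; True = inside the FOV."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("FOV mask must be 2-D")
        if not m.any():
            raise NoRecordingAreaError("no recording area: mask is empty")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class PatchGrid:
    """Row-major lattice of top-left patch anchors, 0-based (row, col).

    Every anchor's half-open footprint ``[r, r+size) x [c, c+size)`` lies fully
    inside the image, and — when built from a mask — fully inside the FOV.
    """

    anchors: tuple[tuple[int, int], ...]
    patch_size: int = PATCH_SIZE
    stride: int = PATCH_STRIDE
    image_shape: tuple[int, int] = (576, 576)

    def __len__(self) -> int:
        return len(self.anchors)

    def footprint(self, anchor: tuple[int, int]) -> tuple[slice, slice]:
        r, c = anchor
        return slice(r, r + self.patch_size), slice(c, c + self.patch_size)

    def contains_anchor(self, anchor: tuple[int, int]) -> bool:
        r, c = anchor
        h, w = self.image_shape
        return (
            r % self.stride == 0
            and c % self.stride == 0
            and 0 <= r <= h - self.patch_size
            and 0 <= c <= w - self.patch_size
        )


@dataclass(frozen=True)
class PatchAnnotation:
    """One expert label ('clean' or 'dirty') at one grid anchor of one frame."""

    frame_id: str
    video_id: str
    anchor: tuple[int, int]
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        object.__setattr__(self, "anchor", (int(self.anchor[0]), int(self.anchor[1])))


def load_frame(path: str | Path, frame_id: str | None = None, video_id: str = "") -> FrameImage:
    """Read a PNG/JPEG frame as 8-bit RGB."""
    path = Path(path)
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return FrameImage(px, frame_id=frame_id or path.stem, video_id=video_id)


def detect_fov_mask(frame: FrameImage, intensity_threshold: int = 10) -> FovMask:
    """Detect the circular recording area by thresholding away the black border.

    A pixel is inside the FOV candidate region when its maximum channel
    intensity exceeds ``intensity_threshold``.  The candidate region is then
    reduced to its largest connected component and holes are filled, so dark
    structures inside the FOV (lumen hole, shadows) stay inside the mask.

    Raises
    ------
    NoRecordingAreaError
        If no pixel exceeds the threshold (an all-black frame).
    """
    bright = frame.pixels.max(axis=2) > intensity_threshold
    if not bright.any():
        raise NoRecordingAreaError("no recording area: frame is entirely black")
    labels, n = ndimage.label(bright)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        bright = labels == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(bright)
    return FovMask(filled)


def load_fov_mask(path: str | Path) -> FovMask:
    """Read a precomputed mask from a single-channel PNG (nonzero = inside FOV)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return FovMask(arr > 0)


def build_patch_grid(
    mask: FovMask, patch_size: int = PATCH_SIZE, stride: int = PATCH_STRIDE
) -> PatchGrid:
    """Build the overlapping patch lattice fully contained in the FOV.

    Anchors lie at multiples of ``stride``; an anchor is admitted only when its
    whole ``patch_size`` footprint is inside the mask.  Anchors are returned in
    row-major order.

    Raises
    ------
    ValueError
        If no patch fits inside the FOV.
    """
    m = mask.mask
    h, w = m.shape
    # Integral image gives the count of FOV pixels in any rectangle in O(1).
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
    full = patch_size * patch_size
    anchors = []
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            count = (
                integral[r + patch_size, c + patch_size]
                - integral[r, c + patch_size]
                - integral[r + patch_size, c]
                + integral[r, c]
            )
            if count == full:
                anchors.append((r, c))
    if not anchors:
        raise ValueError("FOV too small for one patch")
    return PatchGrid(anchors=tuple(anchors), patch_size=patch_size, stride=stride,
                     image_shape=(h, w))


def extract_patches(frame: FrameImage, grid: PatchGrid) -> np.ndarray:
    """Extract normalised patch tensors, one per anchor, in grid order.

    Returns an array of shape (n_patches, size, size, 3) with float32 values in
    [0, 1] (channel intensity / 255, no other preprocessing).
    """
    if frame.shape != grid.image_shape:
        raise ValueError(
            f"grid built for image shape {grid.image_shape}, frame is {frame.shape}"
        )
    out = np.empty((len(grid), grid.patch_size, grid.patch_size, 3), dtype=np.float32)
    for i, anchor in enumerate(grid.anchors):
        rs, cs = grid.footprint(anchor)
        out[i] = frame.pixels[rs, cs].astype(np.float32) / 255.0
    return out


_ANNOTATION_HEADER = ["frame_id", "video_id", "row", "col", "label"]


def write_annotations(annotations: list[PatchAnnotation], path: str | Path) -> None:
    """Write annotations as CSV ``frame_id,video_id,row,col,label``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_HEADER)
        for a in annotations:
            writer.writerow([a.frame_id, a.video_id, a.anchor[0], a.anchor[1], a.label])


def read_annotations(path: str | Path, stride: int = PATCH_STRIDE) -> list[PatchAnnotation]:
    """Read annotations, validating labels and on-grid anchors.

    Raises
    ------
    ValueError
        Naming the offending row for an unknown label or an anchor not on the
        stride lattice.
    """
    out: list[PatchAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _ANNOTATION_HEADER:
            raise ValueError(f"expected header {_ANNOTATION_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            frame_id, video_id, r, c, label = row
            if label not in LABELS:
                raise ValueError(f"row {lineno}: unknown label {label!r}")
            r, c = int(r), int(c)
            if r % stride != 0 or c % stride != 0 or r < 0 or c < 0:
                raise ValueError(f"row {lineno}: anchor ({r}, {c}) off grid (stride {stride})")
            out.append(PatchAnnotation(frame_id, video_id, (r, c), label))
    return out
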