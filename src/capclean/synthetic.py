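"""Synthetic capsule-endoscopy-like frames and rating studies.

Every stage of the pipeline is testable without any download: frames with a
circular field of view on a black background, a textured pinkish "mucosa"
interior, and painted "intestinal content" regions (smooth bile-like blobs,
bright-rimmed bubble clusters, high-frequency brown debris) with exact
ground-truth masks.  Textures are sums of smoothed random lattices (value
noise); photo-realism is not the goal — learnable class structure and exact
ground truth are.

A separate generator emulates a rating study: per-frame mean probabilities
drawn uniformly, expert scores derived from a true threshold triple and
perturbed by adjacent-category flips with a controllable rate.  It drives the
threshold-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .agreement import RatingTable
from .geometry import (
    FovMask,
    FrameImage,
    PatchAnnotation,
    PatchGrid,
    build_patch_grid,
    extract_patches,
)
from .scoring import ThresholdTriple, categorize_array

__all__ = [
    "SyntheticFrameParams",
    "GroundTruth",
    "generate_frame",
    "derive_patch_labels",
    "generate_dataset",
    "generate_labeled_patches",
    "generate_rating_study",
]

CONTENT_TYPES = ("bile_blob", "bubble_cluster", "debris")


@dataclass(frozen=True)
class SyntheticFrameParams:
    size: int = 576
    fov_radius: int = 280
    dirty_fraction: float = 0.0
    content_types: tuple[str, ...] = CONTENT_TYPES
    texture_scale: float = 1.0
    lumen_hole: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dirty_fraction <= 1:
            raise ValueError("dirty_fraction must lie in [0, 1]")
        if self.fov_radius >= self.size / 2:
            raise ValueError("FOV radius must be smaller than half the image size")
        unknown = set(self.content_types) - set(CONTENT_TYPES)
        if unknown:
            raise ValueError(f"unknown content types: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    dirty_mask: np.ndarray
    dirty_fraction: float  # realised fraction of the FOV


def _value_noise(shape: tuple[int, int], cells: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [0, 1]: random lattice upsampled with cubic spline."""
    lattice = rng.random((cells, cells))
    zoomed = ndimage.zoom(lattice, (shape[0] / cells, shape[1] / cells), order=3)
    zoomed = zoomed[: shape[0], : shape[1]]
    lo, hi = zoomed.min(), zoomed.max()
    return (zoomed - lo) / (hi - lo + 1e-12)


def _disk(size: int, cr: float, cc: float, radius: float) -> np.ndarray:
    rr, cc_ = np.ogrid[:size, :size]
    return (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2


def _paint_bile_blob(img, dirty, fov, rng, scale):
    size = img.shape[0]
    cr, cc = rng.uniform(size * 0.2, size * 0.8, size=2)
    radius = rng.uniform(40, 110) * scale
    region = _disk(size, cr, cc, radius)
    noise = _value_noise((size, size), 9, rng)
    blob = region & (noise > 0.35) & fov
    blob = ndimage.binary_closing(blob, iterations=2)
    blob = ndimage.binary_opening(blob, iterations=1) & fov
    if not blob.any():
        blob = region & fov
    shade = 0.75 + 0.5 * _value_noise((size, size), 12, rng)
    color = np.array([178.0, 166.0, 38.0])
    img[blob] = np.clip(color * shade[blob, None], 0, 255)
    dirty |= blob
    return blob


def _paint_bubble_cluster(img, dirty, fov, rng, scale):
    size = img.shape[0]
    ccr, ccc = rng.uniform(size * 0.25, size * 0.75, size=2)
    n_bubbles = rng.integers(8, 22)
    painted = np.zeros_like(dirty)
    for _ in range(n_bubbles):
        br = ccr + rng.normal(0, 45 * scale)
        bc = ccc + rng.normal(0, 45 * scale)
        rad = rng.uniform(7, 20) * scale
        outer = _disk(size, br, bc, rad) & fov
        inner = _disk(size, br, bc, max(rad - 3, 1)) & fov
        rim = outer & ~inner
        img[rim] = [235, 230, 205]  # bright specular rim
        interior = np.clip(
            np.array([205.0, 195.0, 150.0]) * rng.uniform(0.85, 1.05), 0, 255
        )
        img[inner] = interior
        painted |= outer
    dirty |= painted
    return painted


def _paint_debris(img, dirty, fov, rng, scale):
    size = img.shape[0]
    cr, cc = rng.uniform(size * 0.2, size * 0.8, size=2)
    radius = rng.uniform(45, 100) * scale
    region = _disk(size, cr, cc, radius) & fov
    speckle = rng.random((size, size))
    base = np.array([96.0, 62.0, 28.0])
    tex = 0.55 + 0.9 * speckle  # high-frequency brown speckle
    img[region] = np.clip(base * tex[region, None], 0, 255)
    dirty |= region
    return region


_PAINTERS = {
    "bile_blob": _paint_bile_blob,
    "bubble_cluster": _paint_bubble_cluster,
    "debris": _paint_debris,
}


def generate_frame(
    params: SyntheticFrameParams,
) -> tuple[FrameImage, FovMask, GroundTruth]:
    """Render one synthetic frame with its FOV mask and ground-truth dirty mask.

    Content elements are added until the realised dirty fraction of the FOV is
    within 0.05 of the target (best effort with a warning-free fallback after
    a bounded number of attempts).  Bit-deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    size = params.size
    center = (size - 1) / 2.0
    fov = _disk(size, center, center, params.fov_radius)

    # mucosa: pinkish-red base modulated by low- and mid-frequency noise
    low = _value_noise((size, size), 6, rng)
    mid = _value_noise((size, size), max(int(24 * params.texture_scale), 8), rng)
    base = np.zeros((size, size, 3))
    base[..., 0] = 150 + 70 * low + 25 * mid
    base[..., 1] = 70 + 45 * low + 20 * mid
    base[..., 2] = 60 + 35 * low + 15 * mid
    img = np.clip(base, 0, 255)
    if params.lumen_hole:
        hr = center + rng.uniform(-70, 70)
        hc = center + rng.uniform(-70, 70)
        hole = _disk(size, hr, hc, rng.uniform(35, 70))
        falloff = ndimage.gaussian_filter(hole.astype(float), 12)
        img *= (1.0 - 0.75 * falloff)[..., None]

    dirty = np.zeros((size, size), dtype=bool)
    fov_area = int(fov.sum())
    target = params.dirty_fraction
    if target > 0:
        for _ in range(400):
            frac = dirty.sum() / fov_area
            if frac >= target - 0.05:
                break
            kind = params.content_types[rng.integers(len(params.content_types))]
            _PAINTERS[kind](img, dirty, fov, rng, params.texture_scale)
        # saturate toward high targets that sparse elements cannot reach
        if dirty.sum() / fov_area < target - 0.05:
            grow = ndimage.binary_dilation(dirty, iterations=10) & fov
            img[grow & ~dirty] = [170, 158, 45]
            dirty |= grow

    img[~fov] = 0
    frame = FrameImage(
        np.clip(np.round(img), 0, 255).astype(np.uint8),
        frame_id=f"synthetic-{params.seed}",
        video_id="",
    )
    gt = GroundTruth(dirty_mask=dirty & fov, dirty_fraction=float(dirty.sum() / fov_area))
    return frame, FovMask(fov), gt


def derive_patch_labels(
    gt: GroundTruth, grid: PatchGrid, frame_id: str = "", video_id: str = ""
) -> list[PatchAnnotation]:
    """Label grid patches from the ground truth, mimicking the expert protocol.

    A patch is 'dirty' only if every pixel of its footprint is in the dirty
    mask, 'clean' only if none is; mixed patches are omitted (unannotated).
    """
    out = []
    for anchor in grid.anchors:
        rs, cs = grid.footprint(anchor)
        n_dirty = int(gt.dirty_mask[rs, cs].sum())
        full = grid.patch_size * grid.patch_size
        if n_dirty == full:
            out.append(PatchAnnotation(frame_id, video_id, anchor, "dirty"))
        elif n_dirty == 0:
            out.append(PatchAnnotation(frame_id, video_id, anchor, "clean"))
    return out


def generate_dataset(
    n_videos: int,
    frames_per_video: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
    size: int = 576,
    dirty_fraction_range: tuple[float, float] = (0.0, 0.7),
):
    """Generate a multi-video frame set with annotations and a fold manifest.

    Videos drift in texture scale and content mix so frames within a video are
    more alike than frames across videos, as in real procedures.  Returns a
    list of (frame, mask, ground_truth, annotations); when ``out_dir`` is
    given, also writes frame/mask PNGs, ``annotations.csv`` and
    ``manifest.csv`` in the package's standard dialects.
    """
    if n_videos < 1:
        raise ValueError("need at least one video")
    master = np.random.default_rng(seed)
    records = []
    manifest = []
    annotations: list[PatchAnnotation] = []
    for v in range(n_videos):
        video_id = f"video{v:03d}"
        tex = master.uniform(0.7, 1.4)
        mix = tuple(
            t for t in CONTENT_TYPES if master.random() > 0.3
        ) or CONTENT_TYPES
        lo, hi = dirty_fraction_range
        for f in range(frames_per_video):
            frame_seed = int(master.integers(0, 2**31 - 1))
            params = SyntheticFrameParams(
                size=size,
                fov_radius=int(size * 280 / 576),
                dirty_fraction=float(master.uniform(lo, hi)),
                content_types=mix,
                texture_scale=tex,
                lumen_hole=bool(master.random() > 0.25),
                seed=frame_seed,
            )
            frame, mask, gt = generate_frame(params)
            frame_id = f"{video_id}_f{f:03d}"
            frame = FrameImage(frame.pixels, frame_id=frame_id, video_id=video_id)
            grid = build_patch_grid(mask)
            ann = derive_patch_labels(gt, grid, frame_id, video_id)
            annotations.extend(ann)
            manifest.append((frame_id, video_id))
            records.append((frame, mask, gt, ann))
    if out_dir is not None:
        from PIL import Image

        from .geometry import write_annotations

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for frame, mask, _, _ in records:
            Image.fromarray(frame.pixels).save(out / f"{frame.frame_id}.png")
            Image.fromarray((mask.mask * 255).astype(np.uint8)).save(
                out / f"{frame.frame_id}_mask.png"
            )
        write_annotations(annotations, out / "annotations.csv")
        with open(out / "manifest.csv", "w", encoding="utf-8") as fh:
            fh.write("frame_id,video_id\n")
            for frame_id, video_id in manifest:
                fh.write(f"{frame_id},{video_id}\n")
    return records


def generate_labeled_patches(
    n_patches: int, seed: int = 0, size: int = 576
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience sampler: ~balanced normalised patches with 0/1 labels.

    Draws frames at mixed dirty fractions and collects pure clean/dirty
    patches until ``n_patches`` are available (0 = clean, 1 = dirty).
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    n_clean = n_dirty = 0
    half = n_patches // 2
    while n_clean + n_dirty < n_patches:
        params = SyntheticFrameParams(
            size=size,
            fov_radius=int(size * 280 / 576),
            dirty_fraction=float(rng.uniform(0.25, 0.6)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frame, mask, gt = generate_frame(params)
        grid = build_patch_grid(mask)
        patches = extract_patches(frame, grid)
        labels = derive_patch_labels(gt, grid)
        anchor_index = {a: i for i, a in enumerate(grid.anchors)}
        for ann in labels:
            y = 1 if ann.label == "dirty" else 0
            if y == 1 and n_dirty >= n_patches - half:
                continue
            if y == 0 and n_clean >= half:
                continue
            xs.append(patches[anchor_index[ann.anchor]])
            ys.append(y)
            n_clean += 1 - y
            n_dirty += y
            if n_clean + n_dirty >= n_patches:
                break
    return np.stack(xs), np.array(ys, dtype=np.int64)


def generate_rating_study(
    n_videos: int,
    frames_per_video: int,
    true_thresholds: ThresholdTriple,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, RatingTable]:
    """Simulate two experts rating frames generated under the scoring model.

    Mean probabilities are uniform on [0, 1]; each expert's score is the true
    categorisation, flipped to an adjacent category with probability
    ``flip_prob`` (clipped at the scale ends).  Returns the per-frame mean
    probabilities and the two-expert rating table.
    """
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = n_videos * frames_per_video
    mean_probs = rng.uniform(0.0, 1.0, size=n)
    true_scores = categorize_array(mean_probs, true_thresholds)
    columns = []
    for _ in range(2):
        scores = true_scores.copy()
        flip = rng.random(n) < flip_prob
        direction = np.where(rng.random(n) < 0.5, -1, 1)
        moved = np.clip(scores + direction, 1, 4)
        # at the scale ends a clipped flip would be a no-op; move inward instead
        moved = np.where(moved == scores, scores - direction, moved)
        scores = np.where(flip, moved, scores)
        columns.append(np.clip(scores, 1, 4))
    frame_ids = tuple(
        f"video{v:03d}_f{f:03d}" for v in range(n_videos) for f in range(frames_per_video)
    )
    video_ids = tuple(
        f"video{v:03d}" for v in range(n_videos) for _ in range(frames_per_video)
    )
    table = RatingTable(
        scores=np.column_stack(columns),
        frame_ids=frame_ids,
        video_ids=video_ids,
        raters=("expert1", "expert2"),
    )
    return mean_probs, table
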