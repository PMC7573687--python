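"""Patch-to-pixel probability interpolation and heat-map rendering.

Each 64x64 patch classified by the network carries one dirty-probability.
Because patches overlap with stride 32, their probabilities form a regular
lattice when planted at the patch centres (anchor + (32, 32)).  A dense
per-pixel probability map is obtained by bilinear interpolation between the
four surrounding planted centres; pixels outside the convex hull of the
centres (and lattice nodes missing because a border patch did not fit in the
field of view) are handled by clamping to the nearest existing centre, so
every FOV pixel receives a value and the frame mean is always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .geometry import FovMask, FrameImage, PatchGrid

__all__ = [
    "PatchProbabilityMap",
    "PixelProbabilityMap",
    "interpolate_pixel_probabilities",
    "mean_dirty_probability",
    "render_heatmap",
    "save_pixel_map_png",
]


@dataclass(frozen=True)
class PatchProbabilityMap:
    """One dirty-probability per grid anchor, in grid order."""

    grid: PatchGrid
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (len(self.grid),):
            raise ValueError(
                f"need one probability per anchor ({len(self.grid)}), got shape {p.shape}"
            )
        if p.size == 0:
            raise ValueError("empty patch probability map")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class PixelProbabilityMap:
    """Dense dirty-probabilities, defined exactly on the FOV (NaN elsewhere)."""

    values: np.ndarray
    mask: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.mask


def _lattice(ppm: PatchProbabilityMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrange planted centre values on their (possibly ragged) lattice.

    Missing nodes are filled with the value of the nearest existing centre
    (nearest in lattice index space), implementing the substitution rule for
    FOV-edge raggedness.
    """
    half = ppm.grid.patch_size // 2
    centers = np.asarray(ppm.grid.anchors) + half
    rows = np.unique(centers[:, 0])
    cols = np.unique(centers[:, 1])
    li = np.searchsorted(rows, centers[:, 0])
    lj = np.searchsorted(cols, centers[:, 1])
    values = np.full((rows.size, cols.size), np.nan)
    values[li, lj] = ppm.probs
    missing = np.isnan(values)
    if missing.any():
        _, (ir, ic) = ndimage.distance_transform_edt(missing, return_indices=True)
        values = values[ir, ic]
    return rows.astype(np.float64), cols.astype(np.float64), values


def interpolate_pixel_probabilities(
    ppm: PatchProbabilityMap, mask: FovMask
) -> PixelProbabilityMap:
    """Bilinearly interpolate patch probabilities to every FOV pixel.

    Planted centres reproduce their patch probabilities exactly; pixels beyond
    the outermost centres take the nearest centre's (clamped) value; output is
    clipped to [0, 1] and NaN outside the FOV.
    """
    rows, cols, lattice = _lattice(ppm)
    h, w = mask.shape
    if np.ptp(ppm.probs) == 0:
        # constant field: interpolation reproduces the constant exactly
        values = np.where(mask.mask, ppm.probs[0], np.nan)
        return PixelProbabilityMap(values=values, mask=mask.mask.copy())
    rr = np.clip(np.arange(h, dtype=np.float64), rows[0], rows[-1])
    cc = np.clip(np.arange(w, dtype=np.float64), cols[0], cols[-1])
    if rows.size == 1 and cols.size == 1:
        dense = np.full((h, w), lattice[0, 0])
    elif rows.size == 1:
        dense = np.tile(np.interp(cc, cols, lattice[0]), (h, 1))
    elif cols.size == 1:
        dense = np.tile(np.interp(rr, rows, lattice[:, 0])[:, None], (1, w))
    else:
        interp = RegularGridInterpolator((rows, cols), lattice, method="linear")
        gr, gc = np.meshgrid(rr, cc, indexing="ij")
        dense = interp(np.stack([gr.ravel(), gc.ravel()], axis=1)).reshape(h, w)
    dense = np.clip(dense, 0.0, 1.0)
    values = np.where(mask.mask, dense, np.nan)
    return PixelProbabilityMap(values=values, mask=mask.mask.copy())


def mean_dirty_probability(pxm: PixelProbabilityMap) -> float:
    """Arithmetic mean of the dirty probability over the FOV pixels."""
    if not pxm.mask.any():
        raise ValueError("no defined pixels")
    return float(np.nanmean(pxm.values[pxm.mask]))


def render_heatmap(
    frame: FrameImage, pxm: PixelProbabilityMap, alpha: float = 0.5, cmap: str = "jet"
) -> np.ndarray:
    """Blend the frame with a colormapped probability map on the FOV.

    ``alpha`` = 0 returns the frame unchanged; 1 shows only the colormap.
    Pixels outside the FOV are never touched.  Returns an 8-bit RGB array.
    """
    if frame.shape != pxm.values.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match map shape {pxm.values.shape}"
        )
    import matplotlib

    cm = matplotlib.colormaps[cmap]
    filled = np.where(pxm.mask, pxm.values, 0.0)
    colors = (cm(filled)[..., :3] * 255.0)
    out = frame.pixels.astype(np.float64)
    blend = (1.0 - alpha) * out + alpha * colors
    out[pxm.mask] = blend[pxm.mask]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def save_pixel_map_png(pxm: PixelProbabilityMap, path) -> None:
    """Export the map as 16-bit grayscale PNG (value = round(p * 65535), 0 outside FOV)."""
    from PIL import Image

    arr = np.where(pxm.mask, np.round(pxm.values * 65535.0), 0.0).astype(np.uint16)
    Image.fromarray(arr).save(path)
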