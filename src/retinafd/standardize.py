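"""Fundus image standardization.

A fundus photograph shows a circular field of view (FOV) on a black
background; resolution, FOV size and placement differ between cameras, and
the top/bottom circular segments are often clipped.  Standardization makes
every image directly comparable: extract the FOV mask, find the square
bounding box whose inscribed circle is the FOV (padding any clipped
segment with black), crop, and resize to a fixed side (default 1024).
After this step the FOV circle is inscribed and centered, which both the
segmentation network and the fractal-dimension measurement assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize as _sk_resize


class NoFovError(ValueError):
    """No field-of-view region found in the image."""


@dataclass(frozen=True)
class FovMask:
    """Binary FOV mask aligned to the source image.

    ``centroid`` is (row, col) in real pixels; ``diameter`` is the larger
    of the mask's row and column extents — with clipped top/bottom
    segments the column extent is the uncut chord and hence the true
    circle diameter.
    """

    mask: np.ndarray
    centroid: tuple[float, float]
    diameter: float


@dataclass(frozen=True)
class BoundingBox:
    """Square pixel box, 0-based half-open [top, bottom) x [left, right).

    Coordinates may lie outside the image frame; the excess is black-padded
    at crop time.
    """

    top: int
    left: int
    bottom: int
    right: int

    @property
    def side(self) -> int:
        return self.bottom - self.top

    def __post_init__(self):
        if self.bottom - self.top != self.right - self.left:
            raise ValueError("bounding box must be square")


@dataclass(frozen=True)
class StandardizedImage:
    """Square color image with the FOV circle inscribed and centered."""

    pixels: np.ndarray  # (S, S, 3) uint8
    fov_mask: np.ndarray  # (S, S) bool

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def _as_float_gray(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Luma-style grayscale plus the declared channel maximum."""
    img = np.asarray(image)
    if img.ndim == 2:
        gray = img.astype(np.float64)
    elif img.ndim == 3:
        gray = img.astype(np.float64).mean(axis=2)
    else:
        raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")
    max_value = 255.0 if img.dtype == np.uint8 else float(max(img.max(), 1e-12))
    return gray, max_value


def extract_fov_mask(image: np.ndarray, threshold_fraction: float = 0.06) -> FovMask:
    """Extract the binary FOV mask of a fundus photograph.

    The FOV is recovered as the largest connected bright region after
    thresholding at ``threshold_fraction`` of the maximum intensity and a
    morphological closing (disc radius 1% of the smaller image dimension).

    Raises
    ------
    NoFovError
        If no pixel exceeds the threshold.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    gray, max_value = _as_float_gray(image)
    if gray.shape[0] < 1 or gray.shape[1] < 1:
        raise ValueError("empty image")
    fg = gray > threshold_fraction * max_value
    if not fg.any():
        raise NoFovError("no FOV found: no pixel above the intensity threshold")
    radius = max(1, int(round(0.01 * min(gray.shape))))
    # pad before closing: the FOV may be clipped by the frame and the
    # erosion half of the closing must not eat the border
    padded = np.pad(fg, radius, mode="edge")
    fg = ndimage.binary_closing(padded, structure=disk(radius))[
        radius:-radius, radius:-radius]
    labels, n = ndimage.label(fg)
    if n == 0:
        raise NoFovError("no FOV found after morphological cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    extent_r = rows[-1] - rows[0] + 1
    extent_c = cols[-1] - cols[0] + 1
    centroid = ndimage.center_of_mass(mask)
    return FovMask(mask=mask, centroid=(float(centroid[0]), float(centroid[1])),
                   diameter=float(max(extent_r, extent_c)))


def _round_half_up(x: float) -> int:
    # ties round toward +inf so an already-centered even-diameter FOV
    # crops to the identity box
    return int(math.floor(x + 0.5))


def locate_bounding_box(mask: FovMask) -> BoundingBox:
    """Square box of side = FOV diameter (rounded up to even), centered on
    the mask centroid.  The box may extend past the image frame; any
    missing circular segment will be black-padded by :func:`crop_and_pad`.
    """
    side = int(math.ceil(mask.diameter))
    if side % 2:
        side += 1
    if side <= 0:
        raise ValueError("FOV diameter must be positive")
    cr, cc = mask.centroid
    top = _round_half_up(cr - side / 2.0)
    left = _round_half_up(cc - side / 2.0)
    return BoundingBox(top=top, left=left, bottom=top + side, right=left + side)


def crop_and_pad(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop ``box`` from ``image``; regions outside the frame become black."""
    if box.side <= 0:
        raise ValueError("bounding box side must be positive")
    img = np.asarray(image)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    h, w = img.shape[:2]
    out = np.zeros((box.side, box.side, img.shape[2]), dtype=img.dtype)
    src_t, src_b = max(box.top, 0), min(box.bottom, h)
    src_l, src_r = max(box.left, 0), min(box.right, w)
    if src_t < src_b and src_l < src_r:
        out[src_t - box.top:src_b - box.top, src_l - box.left:src_r - box.left] = \
            img[src_t:src_b, src_l:src_r]
    return out[..., 0] if squeeze else out


def standardize(image: np.ndarray, out_side: int = 1024,
                threshold_fraction: float = 0.06) -> StandardizedImage:
    """Full standardization: FOV mask -> bounding box -> crop/pad -> resize.

    Returns the resized color image together with the FOV mask at output
    resolution; pixels outside the mask are forced to black.  Color is
    resampled bilinearly, the mask with nearest-neighbor.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    fov = extract_fov_mask(img, threshold_fraction=threshold_fraction)
    box = locate_bounding_box(fov)
    cropped = crop_and_pad(img, box)
    cropped_mask = crop_and_pad(fov.mask.astype(np.uint8), box)
    pixels = _sk_resize(cropped.astype(np.float64), (out_side, out_side),
                        order=1, anti_aliasing=False, preserve_range=True)
    mask = _sk_resize(cropped_mask, (out_side, out_side), order=0,
                      anti_aliasing=False, preserve_range=True).astype(bool)
    pixels[~mask] = 0.0
    return StandardizedImage(pixels=np.clip(np.round(pixels), 0, 255).astype(np.uint8),
                             fov_mask=mask)
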