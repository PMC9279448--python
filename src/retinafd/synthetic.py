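"""Synthetic fundus phantoms and known-fractal fixtures.

Everything downstream of image acquisition is testable without real data:

* :func:`generate_vessel_tree` draws a recursive branching tree inside a
  circular FOV, emulating the fractal branching pattern of the retinal
  vasculature, and returns the exact binary ground-truth mask.
* :func:`render_phantom` paints that tree as dark vessels on an
  orange-hued retinal background with a bright optic disc, black outside
  the FOV — a valid input to the standardization and segmentation stages.
* :func:`degrade` applies severity-parameterized quality defects (blur,
  an overexposure "milky-white" veil, uneven illumination, a cropped
  field, vanishing thin vessels); severity 0 is the identity.
* :func:`known_fractal` rasterizes sets of analytically known dimension
  (line 1, filled disc 2, point 0, Sierpinski gasket log3/log2, Koch
  curve log4/log3) as oracles for the box-counting estimator.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon

from retinafd.standardize import StandardizedImage

DEGRADATION_KINDS = ("blur", "overexposure", "uneven_illumination",
                     "crop_fov", "thin_vessels")

KNOWN_FRACTALS = {
    "line": 1.0,
    "disc": 2.0,
    "point": 0.0,
    "sierpinski": math.log(3) / math.log(2),
    "koch": math.log(4) / math.log(3),
}


@dataclass(frozen=True)
class TreeParams:
    """Parameters of the recursive branching vessel tree.

    Lengths and widths are expressed at the reference side of 1024 pixels
    and scale linearly with the rendered side.
    """

    depth: int = 9
    branch_angle: float = 40.0      # degrees between sibling branches
    length_ratio: float = 0.78      # child length / parent length
    initial_width: float = 8.0      # px at side 1024
    width_taper: float = 0.80       # child width / parent width
    n_roots: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.length_ratio < 1.0:
            raise ValueError("length_ratio must lie in (0, 1)")
        if not 0.0 < self.width_taper <= 1.0:
            raise ValueError("width_taper must lie in (0, 1]")


@dataclass(frozen=True)
class DegradationSpec:
    kind: str
    severity: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in DEGRADATION_KINDS:
            raise ValueError(f"unknown degradation {self.kind!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")


def _stamp_segment(canvas: np.ndarray, p0, p1, width: float) -> None:
    """Draw a thick line segment as a filled rectangle plus end caps."""
    r0, c0 = p0
    r1, c1 = p1
    length = math.hypot(r1 - r0, c1 - c0)
    half = max(width / 2.0, 0.5)
    if length < 1e-9:
        rr, cc = _draw_disk((r0, c0), half, shape=canvas.shape)
        canvas[rr, cc] = True
        return
    nr, nc = -(c1 - c0) / length, (r1 - r0) / length  # unit normal
    rr, cc = _draw_polygon(
        [r0 + nr * half, r1 + nr * half, r1 - nr * half, r0 - nr * half],
        [c0 + nc * half, c1 + nc * half, c1 - nc * half, c0 - nc * half],
        shape=canvas.shape)
    canvas[rr, cc] = True
    for p in (p0, p1):
        rr, cc = _draw_disk(p, half, shape=canvas.shape)
        canvas[rr, cc] = True


def generate_vessel_tree(params: TreeParams | None = None, side: int = 1024) -> np.ndarray:
    """Binary ground-truth vessel tree inside the inscribed FOV circle.

    ``n_roots`` trunks start on the FOV boundary heading inward; each
    branch splits into two children rotated +/- branch_angle/2 (with seeded
    jitter), lengths and widths tapering geometrically, ``depth`` levels
    deep.  Branches stop at the FOV rim, so the tree lies fully inside
    the circle.
    """
    p = params or TreeParams()
    rng = np.random.default_rng(p.seed)
    canvas = np.zeros((side, side), dtype=bool)
    center = (side - 1) / 2.0
    fov_r = side / 2.0
    scale = side / 1024.0
    base_len = 0.34 * fov_r

    def inside(pt) -> bool:
        return math.hypot(pt[0] - center, pt[1] - center) <= fov_r * 0.985

    def grow(pt, heading, length, width, depth):
        if depth == 0 or length < 1.0 or width < 0.6:
            return
        end = (pt[0] + length * math.sin(heading), pt[1] + length * math.cos(heading))
        if not inside(end):
            # shorten to stay within the rim, then stop
            for frac in (0.7, 0.4, 0.2):
                trial = (pt[0] + frac * length * math.sin(heading),
                         pt[1] + frac * length * math.cos(heading))
                if inside(trial):
                    _stamp_segment(canvas, pt, trial, width)
                    return
            return
        _stamp_segment(canvas, pt, end, width)
        spread = math.radians(p.branch_angle) / 2.0
        for sign in (-1.0, 1.0):
            jitter = rng.normal(0.0, math.radians(7.0))
            grow(end, heading + sign * spread + jitter,
                 length * p.length_ratio * rng.uniform(0.85, 1.15),
                 width * p.width_taper, depth - 1)

    # evenly spaced entry points (jittered): the retinal arcades leave the
    # optic disc in all directions, so every quadrant carries vessels
    phase = rng.uniform(0.0, 2.0 * math.pi)
    for k in range(p.n_roots):
        theta = phase + 2.0 * math.pi * k / p.n_roots + rng.normal(0.0, 0.15)
        start = (center + 0.97 * fov_r * math.sin(theta),
                 center + 0.97 * fov_r * math.cos(theta))
        heading = theta + math.pi + rng.normal(0.0, 0.25)  # inward
        grow(start, heading, base_len, p.initial_width * scale, p.depth)
    return canvas


def _fov_geometry(side: int):
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    center = (side - 1) / 2.0
    dist = np.hypot(rr - center, cc - center)
    return rr, cc, center, dist


def render_phantom(tree: np.ndarray | None = None, side: int = 1024,
                   seed: int = 0, params: TreeParams | None = None):
    """Color fundus phantom plus its exact ground-truth vessel mask.

    Orange-hued background disc with a soft radial falloff and mild
    texture noise, darker red-brown vessel strokes from ``tree``, a
    bright optic-disc disc on the horizontal midline, black exterior.
    """
    if tree is None:
        p = params or TreeParams(seed=seed)
        tree = generate_vessel_tree(p, side=side)
    tree = np.asarray(tree, dtype=bool)
    side = tree.shape[0]
    rng = np.random.default_rng(seed + 7919)
    rr, cc, center, dist = _fov_geometry(side)
    fov = dist <= side / 2.0
    falloff = 1.0 - 0.25 * (dist / (side / 2.0)) ** 2
    img = np.zeros((side, side, 3), dtype=np.float64)
    bg = np.array([205.0, 120.0, 55.0])
    for ch in range(3):
        img[..., ch] = bg[ch] * falloff
    img += rng.normal(0.0, 3.0, size=img.shape)
    # soften vessel edges slightly so they look photographic
    vessel_soft = ndimage.gaussian_filter(tree.astype(np.float64), sigma=0.7 * side / 1024)
    vessel_soft = np.clip(vessel_soft * 1.4, 0.0, 1.0)
    vessel_color = np.array([115.0, 38.0, 28.0])
    for ch in range(3):
        img[..., ch] = img[..., ch] * (1 - vessel_soft) + vessel_color[ch] * vessel_soft
    od_center = (center, center + 0.55 * side / 2.0)
    od_radius = 0.085 * side
    od = np.clip(1.0 - np.hypot(rr - od_center[0], cc - od_center[1]) / od_radius, 0.0, 1.0)
    od = np.clip(od * 2.5, 0.0, 1.0)
    od_color = np.array([245.0, 215.0, 140.0])
    for ch in range(3):
        img[..., ch] = img[..., ch] * (1 - 0.85 * od) + od_color[ch] * 0.85 * od
    img[~fov] = 0.0
    image = StandardizedImage(pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
                              fov_mask=fov)
    return image, tree.astype(np.uint8)


def degrade(image: StandardizedImage, spec: DegradationSpec) -> StandardizedImage:
    """Apply one severity-parameterized quality defect.

    Severity 0 returns a pixel-identical copy.  All defects preserve the
    black exterior and square geometry.
    """
    if spec.severity == 0.0:
        return StandardizedImage(pixels=image.pixels.copy(),
                                 fov_mask=image.fov_mask.copy())
    side = image.side
    img = image.pixels.astype(np.float64)
    fov = image.fov_mask.copy()
    s = spec.severity
    if spec.kind == "blur":
        sigma = s * 0.006 * side
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    elif spec.kind == "overexposure":
        rr, cc, center, dist = _fov_geometry(side)
        rel = np.clip(dist / (side / 2.0), 0.0, 1.0)
        veil = s * np.clip(0.35 + 0.75 * rel, 0.0, 1.0)
        img = img * (1 - veil[..., None]) + 255.0 * veil[..., None]
    elif spec.kind == "uneven_illumination":
        rr, cc, center, dist = _fov_geometry(side)
        gain = 1.0 + s * 0.9 * (cc - center) / (side / 2.0)
        img = img * gain[..., None]
    elif spec.kind == "crop_fov":
        cut = int(round(side * (1.0 - 0.5 * s)))
        img[:, cut:] = 0.0
        fov[:, cut:] = False
    elif spec.kind == "thin_vessels":
        size = max(3, int(round(0.008 * side)))
        closed = np.stack([ndimage.grey_closing(img[..., ch], size=(size, size))
                           for ch in range(3)], axis=-1)
        img = img * (1 - s) + closed * s
    img[~image.fov_mask] = 0.0
    if spec.kind == "crop_fov":
        img[~fov] = 0.0
    return StandardizedImage(pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
                             fov_mask=fov)


# --- known-dimension fixtures ------------------------------------------


def _koch_segments(p0, p1, depth):
    if depth == 0:
        return [(p0, p1)]
    (x0, y0), (x1, y1) = p0, p1
    dx, dy = (x1 - x0) / 3.0, (y1 - y0) / 3.0
    a = (x0 + dx, y0 + dy)
    b = (x0 + 2 * dx, y0 + 2 * dy)
    # apex of the equilateral bump on the left of the travel direction
    apex = (a[0] + dx / 2.0 - dy * math.sqrt(3) / 2.0,
            a[1] + dy / 2.0 + dx * math.sqrt(3) / 2.0)
    segs = []
    for q0, q1 in (((x0, y0), a), (a, apex), (apex, b), (b, (x1, y1))):
        segs.extend(_koch_segments(q0, q1, depth - 1))
    return segs


def known_fractal(name: str, side: int = 1024) -> np.ndarray:
    """Deterministic rasterization of a set with known box dimension."""
    if name not in KNOWN_FRACTALS:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(KNOWN_FRACTALS)}")
    if name in ("sierpinski", "koch") and side < 256:
        raise ValueError(f"{name} requires side >= 256")
    mask = np.zeros((side, side), dtype=bool)
    if name == "line":
        mask[side // 2, :] = True
    elif name == "point":
        mask[side // 2, side // 2] = True
    elif name == "disc":
        rr, cc = _draw_disk((side / 2.0, side / 2.0), side * 400.0 / 1024.0,
                            shape=mask.shape)
        mask[rr, cc] = True
    elif name == "sierpinski":
        # exact self-similar gasket on the largest power-of-two subgrid
        n = 2 ** int(math.floor(math.log2(side)))
        y, x = np.mgrid[0:n, 0:n]
        mask[:n, :n] = (x & y) == 0
    elif name == "koch":
        depth = 6 if side >= 768 else 5
        margin = side * 0.02
        y0 = side * 0.7
        segs = _koch_segments((margin, y0), (side - margin, y0), depth)
        for (x0, yy0), (x1, yy1) in segs:
            rr, cc = _draw_line(int(round(yy0)), int(round(x0)),
                                int(round(yy1)), int(round(x1)))
            keep = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
            mask[rr[keep], cc[keep]] = True
    return mask
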