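"""Box-counting fractal dimension of binary vessel masks.

The fractal dimension (FD) quantifies the geometric complexity of the
segmented vasculature: a grid of boxes of side ``eps`` is overlaid on the
mask and the number of occupied boxes N(eps) counted; the FD is the
exponent of the power law N(eps) ~ eps^(-FD), estimated as the OLS slope
of log N(eps) against log(1/eps).  A 1-pixel curve has FD ~ 1, a filled
region FD ~ 2, an empty mask has no defined FD (NaN).

The module also models the six retinal fields — optic disc (OD), macula
(M) and the four quadrants nasal/superior/temporal/inferior (N/S/T/I)
centered on the macula — so the contribution of each field to the overall
FD can be measured by masking it out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

FIELD_LABELS = ("OD", "M", "N", "S", "T", "I")


@dataclass(frozen=True)
class BoxCountCurve:
    """Paired box sizes eps and occupied-box counts N(eps)."""

    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if sizes.shape != counts.shape or sizes.ndim != 1:
            raise ValueError("sizes and counts must be aligned 1-D arrays")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class FractalDimension:
    """Estimated box-counting dimension with its log-log fit quality.

    ``value`` is NaN when the mask is empty (the FD of nothing is
    undefined); downstream quality logic treats that as the lowest
    possible quality.
    """

    value: float
    fit_r2: float
    curve: BoxCountCurve

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class RetinalFieldGeometry:
    """Positions of the six retinal fields in a standardized image.

    ``d`` is the OD-center to macula-center distance; the macula field is
    a disc of radius 0.6 * d.  The four quadrants N/S/T/I are delimited by
    the two 45-degree diagonals through the macula center; the nasal
    quadrant is the one containing the optic disc, temporal the opposite
    one, so laterality is implied by the OD position.
    """

    od_center: tuple[float, float]
    od_radius: float
    macula_center: tuple[float, float]

    @property
    def d(self) -> float:
        return float(math.hypot(self.od_center[0] - self.macula_center[0],
                                self.od_center[1] - self.macula_center[1]))

    @property
    def macula_radius(self) -> float:
        return 0.6 * self.d

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("OD center and macula center must differ")
        if self.od_radius <= 0:
            raise ValueError("od_radius must be positive")


def box_counts(mask: np.ndarray, sizes) -> BoxCountCurve:
    """Count occupied boxes for each box size.

    The grid is anchored at the top-left corner (0, 0); cells at the right
    and bottom edges may be partial.  A box is occupied when it contains
    at least one foreground pixel.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    sizes = np.asarray(sizes, dtype=np.int64)
    if (sizes < 1).any():
        raise ValueError("box sizes must be >= 1")
    if (sizes > max(m.shape)).any():
        raise ValueError("box sizes must not exceed the mask side")
    counts = np.empty(sizes.shape, dtype=np.int64)
    for i, eps in enumerate(sizes):
        eps = int(eps)
        nh = -(-m.shape[0] // eps)
        nw = -(-m.shape[1] // eps)
        padded = np.zeros((nh * eps, nw * eps), dtype=bool)
        padded[:m.shape[0], :m.shape[1]] = m
        occ = padded.reshape(nh, eps, nw, eps).any(axis=(1, 3))
        counts[i] = int(occ.sum())
    return BoxCountCurve(sizes=sizes, counts=counts)


def estimate_fd(curve: BoxCountCurve) -> FractalDimension:
    """OLS slope of log N(eps) versus log(1/eps) over sizes with N > 0.

    Returns NaN (with ``fit_r2`` NaN) when fewer than two usable points
    remain — in particular for an empty mask, where the FD cannot be
    calculated.
    """
    usable = curve.counts > 0
    if usable.sum() < 2:
        return FractalDimension(value=float("nan"), fit_r2=float("nan"), curve=curve)
    x = np.log(1.0 / curve.sizes[usable].astype(np.float64))
    y = np.log(curve.counts[usable].astype(np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return FractalDimension(value=float(slope), fit_r2=r2, curve=curve)


def default_box_sizes(side: int) -> np.ndarray:
    """Geometric ladder of box sizes, ratio sqrt(2), from 2 up to side // 2.

    The ladder spans the full scale range of the mask — the coarse rungs
    anchor the fit so that removing structure anywhere strictly lowers
    the estimate — with two rungs per octave for a stable regression.
    """
    if side < 8:
        raise ValueError("mask side must be >= 8 for the default box sizes")
    sizes = []
    v = 2.0
    while round(v) <= side // 2:
        sizes.append(int(round(v)))
        v *= math.sqrt(2.0)
    return np.unique(np.array(sizes, dtype=np.int64))


def fd_of_mask(mask: np.ndarray, sizes=None) -> FractalDimension:
    """Box-counting FD of a binary mask with the default size ladder."""
    m = np.asarray(mask)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("mask must be square")
    if sizes is None:
        sizes = default_box_sizes(m.shape[0])
    return estimate_fd(box_counts(m, sizes))


def _grids(side: int):
    rr, cc = np.mgrid[0:side, 0:side]
    return rr.astype(np.float64), cc.astype(np.float64)


def field_mask(geometry: RetinalFieldGeometry, field_label: str, side: int) -> np.ndarray:
    """Binary mask of one retinal field in a side x side standardized frame.

    The six fields partition the inscribed FOV circle: the OD disc; the
    macula disc (minus any OD overlap); and the four diagonal quadrants
    around the macula center, minus both discs, clipped to the FOV.
    Boundary pixels on the diagonals belong to the horizontal (N/T)
    quadrants.
    """
    if field_label not in FIELD_LABELS:
        raise ValueError(f"unknown retinal field {field_label!r}; expected one of {FIELD_LABELS}")
    rr, cc = _grids(side)
    center = (side - 1) / 2.0
    fov = (rr - center) ** 2 + (cc - center) ** 2 <= (side / 2.0) ** 2
    odr, odc = geometry.od_center
    mr, mc = geometry.macula_center
    od_disc = (rr - odr) ** 2 + (cc - odc) ** 2 <= geometry.od_radius ** 2
    m_disc = (rr - mr) ** 2 + (cc - mc) ** 2 <= geometry.macula_radius ** 2
    if field_label == "OD":
        return od_disc & fov
    if field_label == "M":
        return m_disc & ~od_disc & fov
    dr = rr - mr
    dc = cc - mc
    horizontal = np.abs(dc) >= np.abs(dr)  # ties -> nasal/temporal
    nasal_sign = 1.0 if odc >= mc else -1.0
    if field_label == "N":
        quad = horizontal & (nasal_sign * dc >= 0)
    elif field_label == "T":
        quad = horizontal & (nasal_sign * dc < 0)
    elif field_label == "S":
        quad = ~horizontal & (dr < 0)
    else:  # "I"
        quad = ~horizontal & (dr >= 0)
    return quad & ~od_disc & ~m_disc & fov


def fd_with_field_removed(mask: np.ndarray, geometry: RetinalFieldGeometry,
                          field_label: str) -> FractalDimension:
    """FD of the mask after zeroing the pixels of one retinal field."""
    m = np.asarray(mask).astype(bool)
    removed = m & ~field_mask(geometry, field_label, m.shape[0])
    return fd_of_mask(removed)
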