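"""Quality classification on the continuous FD scale.

Retinal image quality is graded on a continuous scale from 0 to about
1.7 — the FD of the segmented vasculature.  Poor-quality images yield
sparse vessel segmentations and hence small FD.  The recommended reject
threshold lies in the band [1.45, 1.50]; high-quality images typically
fall in [1.60, 1.70].  Thresholds are configurable so providers can match
their own grading standards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from retinafd import fractal as _fractal
from retinafd import segmentation as _seg
from retinafd.standardize import StandardizedImage as _StandardizedImage
from retinafd.standardize import standardize as _standardize

SUFFICIENT = "sufficient"
INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class QualityThresholds:
    """FD cut points for the three-class Reject < Usable < Good scale."""

    reject_below: float = 1.50
    good_at_or_above: float = 1.60
    labels: tuple[str, str, str] = ("Reject", "Usable", "Good")

    def __post_init__(self):
        if not self.reject_below < self.good_at_or_above:
            raise ValueError("reject_below must be smaller than good_at_or_above")
        if not (0.0 <= self.reject_below and self.good_at_or_above <= 1.7):
            raise ValueError("thresholds must lie within the [0, 1.7] FD scale")


@dataclass(frozen=True)
class QualityReport:
    """Outcome of the full assessment pipeline for one image."""

    fd: float
    class_label: str
    thresholds: QualityThresholds
    backend: str
    fd_r2: float = float("nan")
    vessel_pixels: int = 0
    source: str = ""
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def classify_binary(fd: float, threshold: float) -> str:
    """"insufficient" iff fd < threshold; NaN counts as insufficient."""
    if not 0.0 < threshold < 2.0:
        raise ValueError("threshold must lie in (0, 2)")
    if math.isnan(fd) or fd < threshold:
        return INSUFFICIENT
    return SUFFICIENT


def classify_multiclass(fd: float, thresholds: QualityThresholds | None = None) -> str:
    """Reject if fd < reject_below; Good if fd >= good_at_or_above;
    otherwise Usable.  NaN maps to the lowest class."""
    t = thresholds or QualityThresholds()
    lo, mid, hi = t.labels
    if math.isnan(fd) or fd < t.reject_below:
        return lo
    if fd >= t.good_at_or_above:
        return hi
    return mid


def assess(image, thresholds: QualityThresholds | None = None,
           backend: str = "vesselness", model=None, out_side: int = 1024,
           bin_threshold: float = 0.5, source: str = "") -> QualityReport:
    """End-to-end quality assessment of one fundus image.

    ``image`` is a path or an (H, W, 3) array.  Runs standardize ->
    segment -> binarize -> FD -> classify and returns a structured
    report; stage failures are captured in ``report.error`` with the
    lowest quality class, never raised, so batch runs always complete.
    """
    t = thresholds or QualityThresholds()
    try:
        if isinstance(image, (str,)) or hasattr(image, "__fspath__"):
            import imageio.v3 as iio
            source = source or str(image)
            image = np.asarray(iio.imread(image))
            if image.ndim == 3 and image.shape[2] == 4:
                image = image[..., :3]
        if isinstance(image, _StandardizedImage) and image.side == out_side:
            std = image
        else:
            pixels = getattr(image, "pixels", image)
            std = _standardize(pixels, out_side=out_side)
        probs = _seg.segment(std, backend=backend, model=model)
        mask = _seg.binarize(probs, threshold=bin_threshold)
        fd = _fractal.fd_of_mask(mask)
        return QualityReport(
            fd=fd.value,
            class_label=classify_multiclass(fd.value, t),
            thresholds=t, backend=backend, fd_r2=fd.fit_r2,
            vessel_pixels=int(mask.sum()), source=source)
    except Exception as exc:  # structured failure, lowest class
        return QualityReport(fd=float("nan"), class_label=t.labels[0],
                             thresholds=t, backend=backend, source=source,
                             error=f"{type(exc).__name__}: {exc}")
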