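"""Classical vesselness backend.

A multiscale Hessian ridge filter (Frangi) on the green channel — where
vessel contrast is strongest in fundus photographs — highlights dark
tubular structures.  The response is normalized to [0, 1] inside the FOV
and zeroed outside.  This backend needs no trained weights, so the full
quality pipeline runs out of the box; a trained network can replace it
for higher segmentation fidelity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import frangi

DEFAULT_SCALES = (1, 2, 4, 8)

# Frangi responses on-vessel are typically O(0.1-0.5); dividing by this
# fixed scale maps a solid vessel response to probability ~1 while the
# background stays near 0.  A fixed scale (rather than max-normalization)
# keeps the map comparable across images: weak responses on degraded
# images yield uniformly low probabilities instead of being stretched.
RESPONSE_SCALE = 0.1


def vesselness_probability(image: np.ndarray, fov_mask: np.ndarray | None = None,
                           scales=DEFAULT_SCALES) -> np.ndarray:
    """Vessel probability map from the multiscale Frangi ridge response."""
    img = np.asarray(image, dtype=np.float64)
    green = img[..., 1] if img.ndim == 3 else img
    if green.max() > 1.5:
        green = green / 255.0
    if fov_mask is None:
        fov_mask = green > 0.02
    fov_mask = np.asarray(fov_mask, dtype=bool)
    # Erode the FOV rim: the circle edge is itself a strong ridge.
    margin = max(3, green.shape[0] // 100)
    interior = ndimage.binary_erosion(fov_mask, iterations=margin)
    resp = frangi(green, sigmas=scales, black_ridges=True)
    resp[~interior] = 0.0
    return np.clip(resp / RESPONSE_SCALE, 0.0, 1.0)
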