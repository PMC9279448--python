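"""Vessel segmentation: the encoder-decoder network, its training loop,
the classical vesselness fallback, and the probability-map utilities."""

from __future__ import annotations

import numpy as np

from retinafd.segmentation.model import (
    SegmentationModelConfig,
    VesselSegmenter,
    WeightsRequiredError,
    bce_loss,
    build_model,
)
from retinafd.segmentation.train import augment, train
from retinafd.segmentation.vesselness import vesselness_probability

BACKENDS = ("cnn", "vesselness")


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary vessel mask (>= rule)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(pred) >= threshold).astype(np.uint8)


def segment(image, backend: str = "vesselness", model: VesselSegmenter | None = None,
            fov_mask: np.ndarray | None = None) -> np.ndarray:
    """Vessel probability map of a standardized image.

    ``backend="cnn"`` runs a forward pass of a trained
    :class:`VesselSegmenter`; ``backend="vesselness"`` uses the
    weights-free multiscale ridge filter.
    """
    pixels = getattr(image, "pixels", image)
    if fov_mask is None:
        fov_mask = getattr(image, "fov_mask", None)
    if backend == "cnn":
        if model is None:
            raise WeightsRequiredError(
                "cnn backend requires a trained model: weights required")
        return model.predict(pixels)
    if backend == "vesselness":
        return vesselness_probability(pixels, fov_mask=fov_mask)
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


__all__ = [
    "SegmentationModelConfig", "VesselSegmenter", "WeightsRequiredError",
    "bce_loss", "build_model", "train", "augment", "binarize", "segment",
    "vesselness_probability", "BACKENDS",
]
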