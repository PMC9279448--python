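"""Training loop and data augmentation for the vessel segmenter."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from retinafd.segmentation import nn
from retinafd.segmentation.model import SegmentationModelConfig, VesselSegmenter, bce_loss


def train(model: VesselSegmenter, pairs, config: SegmentationModelConfig | None = None):
    """Train on (image, mask) pairs by Adam on the mean pixelwise binary
    cross entropy; returns the model and the mean loss per epoch.

    Images are (H, W, 3) in [0, 255] or [0, 1]; masks are (H, W) binary.
    Deterministic for a fixed config seed.  ``epochs = 0`` leaves the
    model untouched and returns an empty trace.
    """
    if config is None:
        config = model.config
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training set must contain at least one pair")
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(list(model.layers()), lr=config.learning_rate)
    xs = [model._to_batch(img)[0] for img, _ in pairs]
    ys = [np.asarray(m, dtype=np.float32).reshape(1, *np.asarray(m).shape[-2:])
          for _, m in pairs]
    trace: list[float] = []
    bs = max(1, config.batch_size)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), bs):
            idx = order[start:start + bs]
            x = np.stack([xs[i] for i in idx])
            y = np.stack([ys[i] for i in idx])
            logits = model.forward_logits(x, train=True)
            p = nn.sigmoid(logits)
            losses.append(bce_loss(y, p))
            # gradient of mean BCE at the logits (fused with sigmoid)
            dlogits = (p - y).astype(np.float32) / y.size
            model.backward(dlogits)
            opt.step()
        trace.append(float(np.mean(losses)))
    return model, trace


def _rotate_pair(image: np.ndarray, mask: np.ndarray, angle: float):
    img = ndimage.rotate(image, angle, axes=(0, 1), reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask.astype(np.uint8), angle, axes=(0, 1), reshape=False,
                         order=0, mode="constant", cval=0)
    return img, msk.astype(mask.dtype)


def augment(pairs, n_out: int, seed: int = 0):
    """Expand (image, mask) pairs to ``n_out`` by random rotation and
    horizontal/vertical flipping, applied identically to image and mask
    (nearest-neighbor for the mask so it stays binary).

    The originals are kept; each extra pair records its transform as
    ``(source_index, angle, flip_axis)`` in the returned provenance list.
    """
    pairs = list(pairs)
    if n_out < len(pairs):
        raise ValueError("n_out must be at least the input pair count")
    rng = np.random.default_rng(seed)
    out = list(pairs)
    provenance = [(i, 0.0, None) for i in range(len(pairs))]
    while len(out) < n_out:
        i = int(rng.integers(len(pairs)))
        img, msk = pairs[i]
        angle = float(rng.uniform(-180.0, 180.0))
        flip = rng.choice([None, 0, 1])
        img, msk = _rotate_pair(np.asarray(img), np.asarray(msk), angle)
        if flip is not None:
            img = np.flip(img, axis=int(flip)).copy()
            msk = np.flip(msk, axis=int(flip)).copy()
        out.append((img, msk))
        provenance.append((i, angle, None if flip is None else int(flip)))
    return out, provenance
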