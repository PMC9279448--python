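"""Encoder-decoder vessel segmentation network.

The model maps a standardized S x S x 3 color fundus image to an S x S
vessel probability map in [0, 1].  Five encoding blocks (two 3x3
conv + batch-norm + ReLU each, followed by 2x2 max pooling) with output
channels 32, 64, 128, 256, 512 mirror five decoding blocks (2x nearest
upsampling, concatenation with the matching encoder skip, two
conv + BN + ReLU) with channels 512, 256, 128, 64, 32, finished by a 1x1
convolution and a sigmoid.  All convolutions use "same" padding so each
block preserves spatial size; the input side must be divisible by 2^5.

Training minimizes the mean pixelwise binary cross entropy between the
predicted probability map and the binary ground-truth vessel mask, using
Adam with an initial learning rate of 2e-4 for 6 epochs (defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from retinafd.segmentation import nn


class WeightsRequiredError(RuntimeError):
    """The CNN backend was selected without trained weights."""


@dataclass
class SegmentationModelConfig:
    input_side: int = 1024
    encoder_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    decoder_channels: tuple[int, ...] = (512, 256, 128, 64, 32)
    kernel: int = 3
    learning_rate: float = 2e-4
    epochs: int = 6
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.encoder_channels or not self.decoder_channels:
            raise ValueError("channel lists must be nonempty")
        if len(self.encoder_channels) != len(self.decoder_channels):
            raise ValueError("encoder and decoder must have the same number of blocks")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        depth = len(self.encoder_channels)
        if self.input_side % (2 ** depth) != 0:
            raise ValueError(
                f"input side {self.input_side} must be divisible by 2^{depth}")


def bce_loss(gt: np.ndarray, pred: np.ndarray, eps: float = 1e-7) -> float:
    """Mean pixelwise binary cross entropy.

    Predictions are clipped to [eps, 1 - eps] before the logarithm.
    """
    g = np.asarray(gt, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-g * np.log(p) - (1.0 - g) * np.log(1.0 - p)))


class VesselSegmenter:
    """The encoder-decoder network as a callable image -> probability map."""

    def __init__(self, config: SegmentationModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc, dec = config.encoder_channels, config.decoder_channels
        k = config.kernel
        self.enc_blocks = []
        cin = 3
        for c in enc:
            self.enc_blocks.append([
                nn.Conv2D(cin, c, k, rng), nn.BatchNorm(c), nn.ReLU(),
                nn.Conv2D(c, c, k, rng), nn.BatchNorm(c), nn.ReLU(),
            ])
            cin = c
        self.pools = [nn.MaxPool2() for _ in enc]
        self.dec_blocks = []
        self.ups = []
        for i, c in enumerate(dec):
            self.ups.append(nn.Upsample2())
            skip_c = enc[len(enc) - 1 - i]
            self.dec_blocks.append([
                nn.Conv2D(cin + skip_c, c, k, rng), nn.BatchNorm(c), nn.ReLU(),
                nn.Conv2D(c, c, k, rng), nn.BatchNorm(c), nn.ReLU(),
            ])
            cin = c
        self.head = nn.Conv2D(cin, 1, 1, rng)

    # --- plumbing -------------------------------------------------------
    def layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.pools
        for up, block in zip(self.ups, self.dec_blocks):
            yield up
            yield from block
        yield self.head

    @staticmethod
    def _to_batch(image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
            x = x.transpose(0, 3, 1, 2)  # NHWC -> NCHW
        if x.max() > 1.5:
            x = x / 255.0
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        self._concat_c = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._concat_c.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            for layer in block:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate through the forward graph, accumulating parameter
        gradients in each layer.  Concatenation gradients split into the
        upsampled path and the encoder skip path."""
        n = len(self.enc_blocks)
        d = self.head.backward(dlogits)
        dskip_for = [None] * n  # indexed by encoder block
        for i in reversed(range(n)):
            for layer in reversed(self.dec_blocks[i]):
                d = layer.backward(d)
            c_up = self._concat_c[i]
            dskip_for[n - 1 - i] = d[:, c_up:]
            d = self.ups[i].backward(d[:, :c_up])
        for j in reversed(range(n)):
            d = self.pools[j].backward(d)
            d = d + dskip_for[j]
            for layer in reversed(self.enc_blocks[j]):
                d = layer.backward(d)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Vessel probability map for one image (H, W, 3) -> (H, W)."""
        x = self._to_batch(image)
        logits = self.forward_logits(x, train=False)
        return nn.sigmoid(logits)[0, 0].astype(np.float64)

    # --- weight (de)serialization --------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v
            if isinstance(layer, nn.BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k] = np.asarray(state[f"layer{i}.{k}"], dtype=np.float32)
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = np.asarray(state[f"layer{i}.running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"layer{i}.running_var"], dtype=np.float32)

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


def build_model(config: SegmentationModelConfig) -> VesselSegmenter:
    """Construct the network from its configuration."""
    return VesselSegmenter(config)
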