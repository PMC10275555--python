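"""Inception-ResNet-v2-topology convolutional feature extractor.

The network follows the canonical Inception-ResNet-v2 layout: an
Inception-v4-style stem, then three stages of residual Inception blocks
(A at the largest grid, B mid-grid, C at the smallest) separated by two
reduction blocks, a final 1x1 convolution and 2-D global average pooling.
Residual branches end in a 1x1 convolution that matches the block's channel
depth before the scaled identity addition; the pooled vector is the feature
tap (1536-dimensional at full scale).

Two scales are provided: ``full`` (299x299 input, canonical widths and
repeats 5/10/5) and ``tiny`` (75x75 input, 1/8 width, repeats 1/2/1) for
desk-scale training and testing.  Grayscale spectrogram images are
replicated to three channels at the input boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .._exceptions import ConfigurationError, ValidationError
from ..spectro import SpectroImage
from .layers import (
    DEFAULT_DTYPE,
    BatchNorm2d,
    ConcatBranches,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    RMSProp,
    ResidualBlock,
    Sequential,
    SGD,
    softmax_cross_entropy,
)

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "FeatureExtractor",
    "build_extractor",
    "extract_features",
    "finetune",
]

_SCALE_PRESETS = {
    "full": dict(input_hw=299, width_mult=1.0, block_repeats=(5, 10, 5)),
    "tiny": dict(input_hw=75, width_mult=0.125, block_repeats=(1, 2, 1)),
}


@dataclass(frozen=True)
class BackboneConfig:
    scale: str = "full"
    input_hw: int | None = None
    width_mult: float | None = None
    block_repeats: tuple[int, int, int] | None = None
    residual_scales: tuple[float, float, float] = (0.17, 0.10, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in _SCALE_PRESETS:
            raise ConfigurationError(f"scale must be one of {list(_SCALE_PRESETS)}")
        preset = _SCALE_PRESETS[self.scale]
        for key in ("input_hw", "width_mult", "block_repeats"):
            if getattr(self, key) is None:
                object.__setattr__(self, key, preset[key])
        if not 0.0 < self.width_mult <= 1.0:
            raise ConfigurationError("width_mult must be in (0, 1]")
        if any(r < 1 for r in self.block_repeats):
            raise ConfigurationError("block repeats must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning settings: learning rate 0.001 with SGD or RMSProp."""

    lr: float = 0.001
    optimizer: str = "sgd"
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "rmsprop"):
            raise ConfigurationError("optimizer must be 'sgd' or 'rmsprop'")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")


def _cbr(rng, c_in, c_out, kernel, stride=1, padding="same") -> Sequential:
    return Sequential(
        Conv2d(c_in, c_out, kernel, stride=stride, padding=padding, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
    )


class _Builder:
    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)

    def w(self, c: int) -> int:
        return max(1, int(round(c * self.cfg.width_mult)))

    def stem(self) -> tuple[Sequential, int]:
        w, rng = self.w, self.rng
        mods = [
            _cbr(rng, 3, w(32), 3, stride=2, padding="valid"),
            _cbr(rng, w(32), w(32), 3, padding="valid"),
            _cbr(rng, w(32), w(64), 3, padding="same"),
            ConcatBranches(
                MaxPool2d(3, 2, "valid"),
                _cbr(rng, w(64), w(96), 3, stride=2, padding="valid"),
            ),
        ]
        c = w(64) + w(96)
        mods.append(
            ConcatBranches(
                Sequential(
                    _cbr(rng, c, w(64), 1),
                    _cbr(rng, w(64), w(96), 3, padding="valid"),
                ),
                Sequential(
                    _cbr(rng, c, w(64), 1),
                    _cbr(rng, w(64), w(64), (7, 1)),
                    _cbr(rng, w(64), w(64), (1, 7)),
                    _cbr(rng, w(64), w(96), 3, padding="valid"),
                ),
            )
        )
        c = 2 * w(96)
        mods.append(
            ConcatBranches(
                _cbr(rng, c, w(192), 3, stride=2, padding="valid"),
                MaxPool2d(3, 2, "valid"),
            )
        )
        return Sequential(*mods), w(192) + c

    def block_a(self, c: int) -> ResidualBlock:
        w, rng = self.w, self.rng
        branches = ConcatBranches(
            _cbr(rng, c, w(32), 1),
            Sequential(_cbr(rng, c, w(32), 1), _cbr(rng, w(32), w(32), 3)),
            Sequential(
                _cbr(rng, c, w(32), 1),
                _cbr(rng, w(32), w(48), 3),
                _cbr(rng, w(48), w(64), 3),
            ),
        )
        mix = 2 * w(32) + w(64)
        expand = Conv2d(mix, c, 1, bias=True, rng=rng)
        return ResidualBlock(Sequential(branches, expand), self.cfg.residual_scales[0])

    def reduction_a(self, c: int) -> tuple[ConcatBranches, int]:
        w, rng = self.w, self.rng
        block = ConcatBranches(
            MaxPool2d(3, 2, "valid"),
            _cbr(rng, c, w(384), 3, stride=2, padding="valid"),
            Sequential(
                _cbr(rng, c, w(256), 1),
                _cbr(rng, w(256), w(256), 3),
                _cbr(rng, w(256), w(384), 3, stride=2, padding="valid"),
            ),
        )
        return block, c + 2 * w(384)

    def block_b(self, c: int) -> ResidualBlock:
        w, rng = self.w, self.rng
        branches = ConcatBranches(
            _cbr(rng, c, w(192), 1),
            Sequential(
                _cbr(rng, c, w(128), 1),
                _cbr(rng, w(128), w(160), (1, 7)),
                _cbr(rng, w(160), w(192), (7, 1)),
            ),
        )
        mix = 2 * w(192)
        expand = Conv2d(mix, c, 1, bias=True, rng=rng)
        return ResidualBlock(Sequential(branches, expand), self.cfg.residual_scales[1])

    def reduction_b(self, c: int) -> tuple[ConcatBranches, int]:
        w, rng = self.w, self.rng
        block = ConcatBranches(
            MaxPool2d(3, 2, "valid"),
            Sequential(
                _cbr(rng, c, w(256), 1),
                _cbr(rng, w(256), w(384), 3, stride=2, padding="valid"),
            ),
            Sequential(
                _cbr(rng, c, w(256), 1),
                _cbr(rng, w(256), w(288), 3, stride=2, padding="valid"),
            ),
            Sequential(
                _cbr(rng, c, w(256), 1),
                _cbr(rng, w(256), w(288), 3),
                _cbr(rng, w(288), w(320), 3, stride=2, padding="valid"),
            ),
        )
        return block, c + w(384) + w(288) + w(320)

    def block_c(self, c: int) -> ResidualBlock:
        w, rng = self.w, self.rng
        branches = ConcatBranches(
            _cbr(rng, c, w(192), 1),
            Sequential(
                _cbr(rng, c, w(192), 1),
                _cbr(rng, w(192), w(224), (1, 3)),
                _cbr(rng, w(224), w(256), (3, 1)),
            ),
        )
        mix = w(192) + w(256)
        expand = Conv2d(mix, c, 1, bias=True, rng=rng)
        return ResidualBlock(Sequential(branches, expand), self.cfg.residual_scales[2])

    def build(self) -> tuple[Sequential, int]:
        rep_a, rep_b, rep_c = self.cfg.block_repeats
        stem, c = self.stem()
        mods: list[Module] = [stem]
        mods += [self.block_a(c) for _ in range(rep_a)]
        red_a, c = self.reduction_a(c)
        mods.append(red_a)
        mods += [self.block_b(c) for _ in range(rep_b)]
        red_b, c = self.reduction_b(c)
        mods.append(red_b)
        mods += [self.block_c(c) for _ in range(rep_c)]
        feature_dim = self.w(1536)
        mods.append(_cbr(self.rng, c, feature_dim, 1))
        mods.append(GlobalAvgPool())
        return Sequential(*mods), feature_dim


class FeatureExtractor:
    """The assembled network with its feature tap at global average pooling."""

    def __init__(self, cfg: BackboneConfig, net: Sequential, feature_dim: int):
        self.cfg = cfg
        self.net = net
        self.feature_dim = feature_dim
        self.finetune_history_: list[dict] = []

    def forward(self, batch: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        return self.net.forward(batch, mode=mode, cache=cache)

    def calibrate(self, images, max_images: int = 128) -> None:
        """Pin batch-norm running statistics to the statistics of one
        deterministic forward pass over (a prefix of) ``images``.

        A randomly initialised network carries placeholder running
        statistics (mean 0, variance 1); calibration replaces them with the
        statistics of real activations so that frozen-feature extraction in
        evaluation mode is well conditioned."""
        batch = _to_batch(images, self.cfg.input_hw)[:max_images]
        self.net.forward(batch, mode="calibrate", cache=False)

    def named_parameters(self):
        return self.net.named_parameters()

    # --- checkpointing --------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"param:{k}": p.value for k, p in self.net.named_parameters()}
        arrays.update({f"buffer:{k}": b for k, b in self.net.named_buffers()})
        header = json.dumps(
            {
                "scale": self.cfg.scale,
                "input_hw": self.cfg.input_hw,
                "width_mult": self.cfg.width_mult,
                "block_repeats": list(self.cfg.block_repeats),
                "residual_scales": list(self.cfg.residual_scales),
                "seed": self.cfg.seed,
                "feature_dim": self.feature_dim,
            }
        )
        np.savez_compressed(path, __config__=np.array(header), **arrays)

    @classmethod
    def load(cls, path: str) -> "FeatureExtractor":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["__config__"]))
            cfg = BackboneConfig(
                scale=header["scale"],
                input_hw=header["input_hw"],
                width_mult=header["width_mult"],
                block_repeats=tuple(header["block_repeats"]),
                residual_scales=tuple(header["residual_scales"]),
                seed=header["seed"],
            )
            fx = build_extractor(cfg)
            params = dict(fx.net.named_parameters())
            for key in data.files:
                if key.startswith("param:"):
                    params[key[6:]].value[...] = data[key]
            buffers = dict(fx.net.named_buffers())
            for key in data.files:
                if key.startswith("buffer:"):
                    buffers[key[7:]][...] = data[key]
        return fx


def build_extractor(cfg: BackboneConfig) -> FeatureExtractor:
    """Construct the network and verify the reduction chain fits the input."""
    net, feature_dim = _Builder(cfg).build()
    net.shape_out((3, cfg.input_hw, cfg.input_hw))  # raises ConfigurationError
    return FeatureExtractor(cfg, net, feature_dim)


def _to_batch(images, input_hw: int) -> np.ndarray:
    """Stack images into an NCHW float batch, replicating grayscale to the
    three input channels and validating spatial size."""
    arrays = []
    for img in images:
        a = img.pixels if isinstance(img, SpectroImage) else np.asarray(img)
        if a.ndim == 2:
            a = a[None, :, :]
        elif a.ndim == 3 and a.shape[2] in (1, 3):
            a = a.transpose(2, 0, 1)
        if a.shape[1] != input_hw or a.shape[2] != input_hw:
            raise ValidationError(
                f"image of size {a.shape[1]}x{a.shape[2]} does not match the "
                f"backbone input size {input_hw}x{input_hw}"
            )
        if a.shape[0] == 1:
            a = np.repeat(a, 3, axis=0)
        arrays.append(a.astype(DEFAULT_DTYPE))
    return np.stack(arrays)


def extract_features(fx: FeatureExtractor, images, batch_size: int | None = None) -> np.ndarray:
    """Evaluation-mode forward pass: one 1536-length (times width multiplier)
    feature row per image, deterministic given the parameters.

    Images are processed one at a time by default: a row then depends only
    on its own image, bit-identically, regardless of batch composition
    (blocked BLAS kernels round identical rows differently at different
    positions of a larger batch).  Pass ``batch_size`` explicitly to trade
    that guarantee for throughput."""
    batch = _to_batch(images, fx.cfg.input_hw)
    if batch_size is None:
        batch_size = 1
    rows = [
        fx.forward(batch[i : i + batch_size], mode="eval", cache=False)
        for i in range(0, batch.shape[0], batch_size)
    ]
    features = np.concatenate(rows, axis=0).astype(np.float64)
    if not np.all(np.isfinite(features)):
        raise ValidationError("non-finite values in extracted features")
    return features


def finetune(
    fx: FeatureExtractor,
    images,
    labels,
    train_cfg: TrainConfig = TrainConfig(),
) -> FeatureExtractor:
    """Fine-tune the extractor on labelled images.

    A temporary softmax head is attached to the feature tap, the mean
    cross-entropy is minimised by full-batch gradient descent (SGD or
    RMSProp, learning rate 0.001 by default) through the whole network, and
    the head is discarded.  The per-epoch loss/accuracy trace is stored on
    ``fx.finetune_history_``.  ``epochs=0`` leaves all parameters unchanged.
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValidationError("fine-tuning requires at least 2 classes")
    batch = _to_batch(images, fx.cfg.input_hw)
    if train_cfg.epochs == 0:
        fx.finetune_history_ = []
        return fx
    rng = np.random.default_rng(train_cfg.seed)
    head = Linear(fx.feature_dim, classes.size, rng=rng)
    params = fx.net.parameters() + head.parameters()
    opt_cls = {"sgd": SGD, "rmsprop": RMSProp}[train_cfg.optimizer]
    opt = opt_cls(params, lr=train_cfg.lr)
    history = []
    for epoch in range(train_cfg.epochs):
        feats = fx.net.forward(batch, mode="train", cache=True)
        logits = head.forward(feats, mode="train", cache=True)
        loss, dlogits = softmax_cross_entropy(logits, y)
        for p in params:
            p.grad[...] = 0.0
        dfeats = head.backward(dlogits)
        fx.net.backward(dfeats)
        opt.step()
        acc = float((logits.argmax(axis=1) == y).mean())
        history.append({"epoch": epoch, "loss": loss, "train_accuracy": acc})
    fx.finetune_history_ = history
    return fx
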