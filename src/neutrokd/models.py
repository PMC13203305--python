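"""Backbone registry: teacher/student network pairs.

Two pairs are shipped: a ResNet-50 / ResNet-18 pair matching the reference
architecture (trainable but GPU-scale), and a tiny CNN pair preserving the
teacher > student capacity relation for desk-scale experiments.  All networks
map standardized ``(N, 3, H, W)`` tensors to ``(N, n_classes)`` logits,
expose a penultimate feature hook (for t-SNE style analysis) and a documented
Grad-CAM++ target layer (the last residual block of the third stage for
ResNets; the last convolution for the tiny CNNs, with a logged warning).

No pretrained weights are available to this package, so every backbone is
He-initialized from the build seed; requesting ``pretrained=True`` raises.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    AvgPoolGlobal,
    BasicBlock,
    BatchNorm2d,
    Bottleneck,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = [
    "BackboneSpec",
    "Network",
    "build",
    "extract_features",
    "target_layer_for_cam",
    "parameter_count",
    "parameter_checksum",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = ("resnet50", "resnet18", "tiny_cnn_large", "tiny_cnn_small")


@dataclass(frozen=True)
class BackboneSpec:
    architecture: str
    n_classes: int
    pretrained: bool = False
    role: str = "student"
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; options: {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.role not in ("teacher", "student"):
            raise ValueError("role must be 'teacher' or 'student'")


class Network(Sequential):
    """A backbone with metadata: CAM target index and feature-layer index."""

    def __init__(self, layers, spec: BackboneSpec, cam_index: int, feature_dim: int):
        super().__init__(layers)
        self.spec = spec
        self.cam_index = cam_index
        self.feature_dim = feature_dim

    def logits(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode forward over a batch, chunked to bound memory."""
        outs = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)


def _tiny_cnn(channels: list[int], spec: BackboneSpec, rng) -> Network:
    layers: list[Module] = []
    cin = 3
    last_conv_idx = 0
    for i, c in enumerate(channels):
        layers.append(Conv2d(cin, c, 3, 1, 1, bias=False, rng=rng))
        last_conv_idx = len(layers) - 1
        layers.append(BatchNorm2d(c))
        layers.append(ReLU())
        if i < 3:  # shrink spatial extent for the first three blocks
            layers.append(MaxPool2d(2))
        cin = c
    layers.append(AvgPoolGlobal())
    layers.append(Linear(cin, spec.n_classes, rng=rng))
    return Network(layers, spec, cam_index=last_conv_idx, feature_dim=cin)


def _resnet(block_cls, counts: list[int], spec: BackboneSpec, rng) -> Network:
    layers: list[Module] = [
        Conv2d(3, 64, 7, 2, 3, bias=False, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, 1),
    ]
    cin = 64
    cam_index = 0
    for stage, (channels, n_blocks) in enumerate(zip((64, 128, 256, 512), counts)):
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(block_cls(cin, channels, stride, rng=rng))
            cin = channels * block_cls.expansion
        if stage == 2:  # last residual block of the third stage
            cam_index = len(layers) - 1
    layers.append(AvgPoolGlobal())
    layers.append(Linear(cin, spec.n_classes, rng=rng))
    return Network(layers, spec, cam_index=cam_index, feature_dim=cin)


def build(spec: BackboneSpec) -> Network:
    """Instantiate a backbone from its spec, deterministically from the seed."""
    if spec.pretrained:
        raise ValueError(
            "pretrained weights are not available; build with pretrained=False "
            "(backbones are He-initialized from the build seed)"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.architecture == "tiny_cnn_small":
        return _tiny_cnn([8, 16, 32], spec, rng)
    if spec.architecture == "tiny_cnn_large":
        return _tiny_cnn([16, 32, 64, 64], spec, rng)
    if spec.architecture == "resnet18":
        return _resnet(BasicBlock, [2, 2, 2, 2], spec, rng)
    return _resnet(Bottleneck, [3, 4, 6, 3], spec, rng)


def extract_features(network: Network, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Penultimate-layer activations (post-pooling, pre-classifier), row per image."""
    feats = []
    for i in range(0, images.shape[0], batch_size):
        network.forward(images[i : i + batch_size], train=False, record=True)
        feats.append(network._outs[-2])  # input to the final Linear
    return np.concatenate(feats, axis=0)


def target_layer_for_cam(network: Network, override: int | None = None) -> int:
    """Index of the Grad-CAM++ target layer within the network's layer list."""
    if override is not None:
        return override
    if network.spec.architecture.startswith("tiny_cnn"):
        logger.warning(
            "%s has no third residual stage; falling back to its last conv layer",
            network.spec.architecture,
        )
    return network.cam_index


def parameter_count(network: Network) -> int:
    return int(sum(p.data.size for p in network.params()))


def parameter_checksum(network: Network) -> str:
    """Hash over all parameters and batch-norm running statistics."""
    h = hashlib.sha256()
    for p in network.params():
        h.update(np.ascontiguousarray(p.data).tobytes())
    for layer in _walk_batchnorms(network):
        h.update(np.ascontiguousarray(layer.running_mean).tobytes())
        h.update(np.ascontiguousarray(layer.running_var).tobytes())
    return h.hexdigest()


def _walk_batchnorms(module):
    if isinstance(module, BatchNorm2d):
        yield module
    for attr in vars(module).values():
        if isinstance(attr, Module):
            yield from _walk_batchnorms(attr)
        elif isinstance(attr, list):
            for item in attr:
                if isinstance(item, Module):
                    yield from _walk_batchnorms(item)


def save_checkpoint(network: Network, path) -> None:
    """Serialize a network; file naming convention <role>_<arch>_<fold>.ckpt."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(network, fh)


def load_checkpoint(path) -> Network:
    with open(path, "rb") as fh:
        return pickle.load(fh)
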