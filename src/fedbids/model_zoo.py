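"""3D DenseNet regression network, freeze policies and weight-set I/O.

The network is the densely connected convolutional architecture
(DenseNet-121 topology) adapted to 3D single-channel volumes with a scalar
regression head: an initial 7³ stride-2 convolution, four dense blocks of
6/12/24/16 layers (growth rate 32, 1³ bottlenecks at 4× growth), compression-
0.5 transitions with 2³ average pooling, and a final adaptive average pool
feeding a 1,024 → 1 fully connected layer.  With bias-free convolutions this
configuration has exactly 11,243,649 trainable parameters, of which 1,025
(1,024 weights + 1 bias) sit in the head.

Transfer learning supports two policies: *shallow* (only the head trains;
the feature extractor, including batch-norm statistics, is frozen bit-exact)
and *deep* (everything trains).
"""

from __future__ import annotations

import io
import json
import struct
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .nn import (
    AvgPool3d,
    BatchNorm3d,
    CheckpointError,
    Conv3d,
    GlobalAvgPool3d,
    Linear,
    MaxPool3d,
    Module,
    ReLU,
)

__all__ = [
    "DenseNetSpec", "FreezePolicy", "DenseNetRegressor", "build_densenet",
    "apply_freeze_policy", "count_trainable", "WeightSet", "CheckpointError",
    "save_weight_set", "load_weight_set",
]


@dataclass(frozen=True)
class DenseNetSpec:
    """Architecture hyperparameters of the 3D DenseNet regressor."""

    spatial_dims: int = 3
    in_channels: int = 1
    out_units: int = 1
    init_features: int = 64
    growth_rate: int = 32
    block_layers: tuple[int, int, int, int] = (6, 12, 24, 16)
    bottleneck_factor: int = 4
    compression: float = 0.5
    conv_bias: bool = False

    def __post_init__(self):
        if self.spatial_dims != 3:
            raise ValueError("only 3D volumes are supported")
        if not (0 < self.compression <= 1):
            raise ValueError("compression must lie in (0, 1]")
        for name in ("in_channels", "out_units", "init_features",
                     "growth_rate", "bottleneck_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def small(cls) -> "DenseNetSpec":
        """Scaled-down preset for desk-scale training on 32³ phantoms."""
        return cls(init_features=16, growth_rate=8, block_layers=(2, 2, 2, 2))

    @property
    def final_features(self) -> int:
        c = self.init_features
        for i, n_layers in enumerate(self.block_layers):
            c += n_layers * self.growth_rate
            if i < len(self.block_layers) - 1:
                c = int(np.floor(c * self.compression))
        return c

    def to_dict(self) -> dict:
        return {
            "spatial_dims": self.spatial_dims,
            "in_channels": self.in_channels,
            "out_units": self.out_units,
            "init_features": self.init_features,
            "growth_rate": self.growth_rate,
            "block_layers": list(self.block_layers),
            "bottleneck_factor": self.bottleneck_factor,
            "compression": self.compression,
            "conv_bias": self.conv_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenseNetSpec":
        d = dict(d)
        if "block_layers" in d:
            d["block_layers"] = tuple(d["block_layers"])
        return cls(**d)


@dataclass(frozen=True)
class FreezePolicy:
    """Which parameters train: 'shallow' = head only, 'deep' = everything."""

    mode: str

    def __post_init__(self):
        if self.mode not in ("shallow", "deep"):
            raise ValueError(f"unknown freeze mode {self.mode!r}")


class _DenseLayer(Module):
    """norm → relu → 1³ bottleneck conv → norm → relu → 3³ conv (growth out)."""

    def __init__(self, in_channels: int, growth: int, bn_size: int,
                 conv_bias: bool):
        super().__init__()
        inter = bn_size * growth
        self.norm1 = BatchNorm3d(in_channels, frozen_stats=True)
        self.relu1 = ReLU()
        self.conv1 = Conv3d(in_channels, inter, 1, bias=conv_bias)
        self.norm2 = BatchNorm3d(inter, frozen_stats=True)
        self.relu2 = ReLU()
        self.conv2 = Conv3d(inter, growth, 3, padding=1, bias=conv_bias)
        self._order = ["norm1", "relu1", "conv1", "norm2", "relu2", "conv2"]

    def forward(self, x):
        for name in self._order:
            x = self._modules[name](x)
        return x

    def backward(self, grad):
        for name in reversed(self._order):
            grad = self._modules[name].backward(grad)
        return grad


class _DenseBlock(Module):
    """Dense connectivity: each layer consumes the running feature stack."""

    def __init__(self, n_layers: int, in_channels: int, growth: int,
                 bn_size: int, conv_bias: bool):
        super().__init__()
        self.in_channels = in_channels
        self.growth = growth
        self.n_layers = n_layers
        for i in range(n_layers):
            setattr(self, f"denselayer{i + 1}",
                    _DenseLayer(in_channels + i * growth, growth, bn_size,
                                conv_bias))
        self.out_channels = in_channels + n_layers * growth

    def forward(self, x):
        feats = [x]
        for i in range(self.n_layers):
            layer = self._modules[f"denselayer{i + 1}"]
            cat = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            feats.append(layer(cat))
        return np.concatenate(feats, axis=1)

    def backward(self, grad):
        g = self.growth
        c0 = self.in_channels
        # split the incoming gradient over [input | layer outputs]
        grads = [np.ascontiguousarray(grad[:, :c0])]
        for i in range(self.n_layers):
            grads.append(np.ascontiguousarray(
                grad[:, c0 + i * g: c0 + (i + 1) * g]))
        for i in range(self.n_layers, 0, -1):
            layer = self._modules[f"denselayer{i}"]
            gin = layer.backward(grads[i])  # grad on concat(x, f1..f_{i-1})
            grads[0] = grads[0] + gin[:, :c0]
            for j in range(1, i):
                grads[j] = grads[j] + gin[:, c0 + (j - 1) * g: c0 + j * g]
        return grads[0]


class _Transition(Module):
    def __init__(self, in_channels: int, out_channels: int, conv_bias: bool):
        super().__init__()
        self.norm = BatchNorm3d(in_channels, frozen_stats=True)
        self.relu = ReLU()
        self.conv = Conv3d(in_channels, out_channels, 1, bias=conv_bias)
        self.pool = AvgPool3d(2)
        self._order = ["norm", "relu", "conv", "pool"]

    def forward(self, x):
        for name in self._order:
            x = self._modules[name](x)
        return x

    def backward(self, grad):
        for name in reversed(self._order):
            grad = self._modules[name].backward(grad)
        return grad


class DenseNetRegressor(Module):
    """The full network: feature extractor plus scalar regression head."""

    def __init__(self, spec: DenseNetSpec):
        super().__init__()
        self.spec = spec
        self.conv0 = Conv3d(spec.in_channels, spec.init_features, 7, stride=2,
                            padding=3, bias=spec.conv_bias,
                            needs_input_grad=False)
        self.norm0 = BatchNorm3d(spec.init_features, frozen_stats=True)
        self.relu0 = ReLU()
        self.pool0 = MaxPool3d(3, stride=2, padding=1)
        order = ["conv0", "norm0", "relu0", "pool0"]
        channels = spec.init_features
        for i, n_layers in enumerate(spec.block_layers):
            block = _DenseBlock(n_layers, channels, spec.growth_rate,
                                spec.bottleneck_factor, spec.conv_bias)
            setattr(self, f"denseblock{i + 1}", block)
            order.append(f"denseblock{i + 1}")
            channels = block.out_channels
            if i < len(spec.block_layers) - 1:
                out_ch = int(np.floor(channels * spec.compression))
                setattr(self, f"transition{i + 1}",
                        _Transition(channels, out_ch, spec.conv_bias))
                order.append(f"transition{i + 1}")
                channels = out_ch
        self.norm5 = BatchNorm3d(channels, frozen_stats=True)
        self.relu5 = ReLU()
        self.gap = GlobalAvgPool3d()
        self.head = Linear(channels, spec.out_units, bias=True)
        order += ["norm5", "relu5", "gap", "head"]
        self._order = order
        self.feature_width = channels

    def init_weights(self, seed: int = 0) -> "DenseNetRegressor":
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, (Conv3d, Linear)):
                m.init_weights(rng)
        return self

    def forward(self, x):
        for name in self._order:
            x = self._modules[name](x)
        return x

    def backward(self, grad):
        head_only = not any(
            p.trainable for name, p in self.named_parameters()
            if not name.startswith("head."))
        if head_only:
            return self.head.backward(grad)
        for name in reversed(self._order):
            grad = self._modules[name].backward(grad)
        return grad

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass (eval mode, no caches)."""
        was_training = self.training
        self.set_training(False)
        out = self.forward(x).reshape(-1)
        self.set_training(was_training)
        return out


def build_densenet(spec: DenseNetSpec | None = None,
                   seed: int = 0) -> DenseNetRegressor:
    """Construct and initialise the regression network."""
    return DenseNetRegressor(spec or DenseNetSpec()).init_weights(seed)


def apply_freeze_policy(model: DenseNetRegressor,
                        policy: FreezePolicy | str) -> DenseNetRegressor:
    """Mark parameters trainable per policy; idempotent and reversible.

    Shallow mode also freezes batch-norm running statistics (the frozen
    layers normalise with their stored statistics), so the feature extractor
    is carried through training bit-identically.
    """
    if isinstance(policy, str):
        policy = FreezePolicy(policy)
    for name, p in model.named_parameters():
        p.trainable = policy.mode == "deep" or name.startswith("head.")
    return model


def count_trainable(model: Module) -> int:
    """Total element count of parameters currently marked trainable."""
    return sum(p.size for _, p in model.named_parameters() if p.trainable)


# ---------------------------------------------------------------------------
# WeightSet: the unit of federation exchange
# ---------------------------------------------------------------------------

class WeightSet(OrderedDict):
    """Ordered map parameter-name → float array (model state snapshot)."""

    @classmethod
    def from_model(cls, model: Module) -> "WeightSet":
        return cls(model.state_dict())

    def apply_to(self, model: Module) -> Module:
        model.load_state_dict(self)
        return model

    def __sub__(self, other: "WeightSet") -> "WeightSet":
        if list(self) != list(other):
            raise CheckpointError("weight sets have different keys")
        return WeightSet((k, self[k] - other[k]) for k in self)

    def allclose(self, other: "WeightSet", atol: float = 0.0) -> bool:
        return (list(self) == list(other) and all(
            np.allclose(self[k], other[k], atol=atol, rtol=0) for k in self))


_MAGIC = b"FBCKPT1\x00"


def save_weight_set(weights: WeightSet, path, meta: dict | None = None) -> None:
    """Serialise a weight set (plus JSON metadata) deterministically."""
    records = []
    blob = io.BytesIO()
    for name, arr in weights.items():
        a = np.ascontiguousarray(arr)
        records.append({"name": name, "dtype": a.dtype.str,
                        "shape": list(a.shape)})
        blob.write(a.tobytes())
    header = json.dumps({"meta": meta or {}, "arrays": records},
                        sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        fh.write(blob.getvalue())


def load_weight_set(path) -> tuple[WeightSet, dict]:
    """Read a checkpoint written by :func:`save_weight_set`."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise CheckpointError(f"{path}: not a fedbids checkpoint")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        ws = WeightSet()
        for rec in header["arrays"]:
            dt = np.dtype(rec["dtype"])
            n = int(np.prod(rec["shape"])) if rec["shape"] else 1
            raw = fh.read(n * dt.itemsize)
            ws[rec["name"]] = np.frombuffer(raw, dtype=dt).reshape(
                rec["shape"]).copy()
    return ws, header["meta"]
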