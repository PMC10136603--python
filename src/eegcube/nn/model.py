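"""3D depthwise-separable CNN backbone, dense head, and checkpoints.

The backbone is a MobileNet-style 3D network: a full 3x3x3 stem convolution
with stride (1,2,2), then five stages of depthwise-separable blocks
(depthwise 3x3x3 + BN + ReLU followed by pointwise 1x1x1 + BN + ReLU) with
repeats [1, 2, 2, 6, 2], and a global average pool producing one feature
per channel.  At width multiplier 1.0 with a 3 x 200 x 64 x 64 input the
stage outputs are

    stem   32 x 200 x 32 x 32
    stage1  64 x 100 x 16 x 16
    stage2 128 x  50 x  8 x  8
    stage3 256 x  25 x  4 x  4
    stage4 512 x  13 x  2 x  2
    stage5 1024 x 13 x  2 x  2
    pool   1024

(ceil-mode same padding is what takes the temporal extent 200 through
100/50/25 to 13).  The dense head is Dense1 (1024, linear) -> Dense2 (256,
ReLU) -> Dense3 (120, ReLU) -> Dense4 (K, softmax); Dense1's activations
are the deep features handed to the hybrid decision heads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers import (
    Adam,
    BatchNorm3d,
    Conv3d,
    DepthwiseConv3d,
    GlobalAvgPool3d,
    Layer,
    Linear,
    ReLU,
    conv_out_len,
    softmax,
)

__all__ = [
    "BackboneConfig",
    "HeadConfig",
    "ConfigError",
    "Backbone3D",
    "MLPHead",
    "Classifier",
    "build_backbone",
    "attach_head",
    "propagate_shapes",
    "save_checkpoint",
    "load_checkpoint",
    "load_pretrained",
    "LoadError",
    "parameter_checksum",
]

# (repeats, stride of first block, base output channels), per stage
DEFAULT_STAGES: tuple[tuple[int, tuple[int, int, int], int], ...] = (
    (1, (2, 2, 2), 64),
    (2, (2, 2, 2), 128),
    (2, (2, 2, 2), 256),
    (6, (2, 2, 2), 512),
    (2, (1, 1, 1), 1024),
)


class ConfigError(ValueError):
    pass


class LoadError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    width_multiplier: float = 1.0
    input_shape: tuple[int, int, int, int] = (3, 200, 64, 64)
    stem_channels: int = 32
    stages: tuple[tuple[int, tuple[int, int, int], int], ...] = DEFAULT_STAGES
    seed: int = 0

    def scaled(self, ch: int) -> int:
        return max(1, int(round(ch * self.width_multiplier)))

    @property
    def feature_dim(self) -> int:
        return self.scaled(self.stages[-1][2])


@dataclass(frozen=True)
class HeadConfig:
    """Dense head widths and class count; Table-layout [1024, 256, 120, K]."""

    n_classes: int
    hidden_widths: tuple[int, ...] = (1024, 256, 120)
    seed: int = 0

    @property
    def widths(self) -> tuple[int, ...]:
        return (*self.hidden_widths, self.n_classes)


def propagate_shapes(config: BackboneConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Analytic forward shape propagation through every stage.

    Independent of the layer implementations: applies the ceil(n/stride)
    rule per dimension.  Raises :class:`ConfigError` naming the first stage
    whose strided input has already collapsed to a single cell.
    """
    c, d, h, w = config.input_shape
    shapes = [("input", (c, d, h, w))]

    def step(name, dims, stride):
        for extent, s in zip(dims, stride):
            if s > 1 and extent < 2:
                raise ConfigError(
                    f"input extent {extent} too small for stride {s} at {name}"
                )
        return tuple(conv_out_len(n, s) for n, s in zip(dims, stride))

    d, h, w = step("stem", (d, h, w), (1, 2, 2))
    shapes.append(("stem", (config.scaled(config.stem_channels), d, h, w)))
    for i, (repeats, stride, out_ch) in enumerate(config.stages, start=1):
        d, h, w = step(f"stage{i}", (d, h, w), stride)
        shapes.append((f"stage{i}", (config.scaled(out_ch), d, h, w)))
    shapes.append(("pool", (config.feature_dim,)))
    return shapes


class _Sequential:
    """Named layer chain with a flat parameter registry."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for _, layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, arr in layer.params.items():
                out[f"{name}.{pname}"] = arr
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, arr in layer.grads.items():
                out[f"{name}.{pname}"] = arr
        return out

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for sname, arr in layer.state().items():
                out[f"{name}.{sname}"] = arr
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for sname in layer.state():
                key = f"{name}.{sname}"
                if sname in layer.params:
                    layer.params[sname][...] = state[key]
                else:  # BN running buffers
                    setattr(layer, sname, state[key].copy())


class Backbone3D(_Sequential):
    """The convolutional feature extractor ending in a global average pool."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        propagate_shapes(config)  # validates stride pyramid
        rng = np.random.default_rng(config.seed)
        layers: list[tuple[str, Layer]] = []
        in_ch = config.input_shape[0]
        stem_ch = config.scaled(config.stem_channels)
        layers += [
            ("stem.conv", Conv3d(in_ch, stem_ch, 3, stride=(1, 2, 2), rng=rng)),
            ("stem.bn", BatchNorm3d(stem_ch)),
            ("stem.relu", ReLU()),
        ]
        ch = stem_ch
        for i, (repeats, stride, out_ch) in enumerate(config.stages, start=1):
            out_ch = config.scaled(out_ch)
            for r in range(repeats):
                s = stride if r == 0 else (1, 1, 1)
                p = f"stage{i}.{r}"
                layers += [
                    (f"{p}.dw", DepthwiseConv3d(ch, 3, stride=s, rng=rng)),
                    (f"{p}.dw_bn", BatchNorm3d(ch)),
                    (f"{p}.dw_relu", ReLU()),
                    (f"{p}.pw", Conv3d(ch, out_ch, 1, rng=rng)),
                    (f"{p}.pw_bn", BatchNorm3d(out_ch)),
                    (f"{p}.pw_relu", ReLU()),
                ]
                ch = out_ch
        layers.append(("pool", GlobalAvgPool3d()))
        super().__init__(layers)

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def forward_batched(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Eval-mode features for a large batch, chunked to bound memory."""
        outs = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def calibrate_bn(self, x: np.ndarray, max_samples: int = 64) -> None:
        """Set batch-norm running statistics from a calibration batch.

        A randomly initialized backbone starts with running mean 0 / var 1,
        which bears no relation to its actual activation scales — without
        correction, eval-mode activations decay through the heavily padded
        late stages.  Pretrained checkpoints carry trained statistics; a
        freshly built backbone is instead calibrated once, before any
        freezing, by propagating (up to) ``max_samples`` inputs and storing
        each BN layer's observed batch statistics.  Weights are untouched.
        """
        h = x[:max_samples].astype(np.float32)
        for _, layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                mean = h.mean(axis=(0, 2, 3, 4))
                var = h.var(axis=(0, 2, 3, 4))
                layer.running_mean = mean.astype(np.float32)
                layer.running_var = var.astype(np.float32)
            h = layer.forward(h, train=False)


class MLPHead:
    """Dense1..Dense4 classifier head; Dense1's output is the feature tap."""

    def __init__(self, in_dim: int, config: HeadConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.widths
        self.dense = []
        prev = in_dim
        for wdt in widths:
            self.dense.append(Linear(prev, wdt, rng=rng))
            prev = wdt
        self.relu = [ReLU() for _ in range(len(widths) - 2)]
        self.in_dim = in_dim

    def forward(self, x: np.ndarray, train: bool = False,
                return_features: bool = False):
        h = self.dense[0].forward(x, train=train)  # Dense1: linear activation
        features = h
        for lin, act in zip(self.dense[1:-1], self.relu):
            h = act.forward(lin.forward(h, train=train), train=train)
        logits = self.dense[-1].forward(h, train=train)
        if return_features:
            return logits, features
        return logits

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.dense[-1].backward(grad)
        for lin, act in zip(reversed(self.dense[1:-1]), reversed(self.relu)):
            grad = lin.backward(act.backward(grad))
        return self.dense[0].backward(grad)

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lin in enumerate(self.dense, start=1):
            for pname, arr in lin.params.items():
                out[f"dense{i}.{pname}"] = arr
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lin in enumerate(self.dense, start=1):
            for pname, arr in lin.grads.items():
                out[f"dense{i}.{pname}"] = arr
        return out

    state = params

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, lin in enumerate(self.dense, start=1):
            for pname in lin.params:
                lin.params[pname][...] = state[f"dense{i}.{pname}"]


class Classifier:
    """Backbone plus dense head: probabilities out, argmax label."""

    def __init__(self, backbone: Backbone3D, head: MLPHead):
        if head.in_dim != backbone.feature_dim:
            raise ConfigError(
                f"head expects {head.in_dim}-d features, backbone emits "
                f"{backbone.feature_dim}-d"
            )
        self.backbone = backbone
        self.head = head

    def forward(self, x: np.ndarray, train: bool = False,
                train_backbone: bool = False, return_features: bool = False):
        feats = self.backbone.forward(x, train=train and train_backbone)
        return self.head.forward(feats, train=train,
                                 return_features=return_features)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        logits = [
            self.forward(x[i : i + batch_size])
            for i in range(0, x.shape[0], batch_size)
        ]
        return softmax(np.concatenate(logits, axis=0))

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def features(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Deep features tapped at Dense 1 (1024-d at the default head)."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            _, f = self.forward(x[i : i + batch_size], return_features=True)
            out.append(f)
        return np.concatenate(out, axis=0)

    def state(self) -> dict[str, np.ndarray]:
        out = {f"backbone.{k}": v for k, v in self.backbone.state().items()}
        out.update({f"head.{k}": v for k, v in self.head.state().items()})
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.backbone.load_state(
            {k[len("backbone."):]: v for k, v in state.items()
             if k.startswith("backbone.")}
        )
        self.head.load_state(
            {k[len("head."):]: v for k, v in state.items()
             if k.startswith("head.")}
        )


def build_backbone(config: BackboneConfig) -> Backbone3D:
    """Construct the seeded backbone; raises ConfigError on a bad pyramid."""
    return Backbone3D(config)


def attach_head(backbone: Backbone3D, head_config: HeadConfig) -> Classifier:
    head = MLPHead(backbone.feature_dim, head_config)
    return Classifier(backbone, head)


def parameter_checksum(state: dict[str, np.ndarray]) -> str:
    """Order-independent digest of a parameter tree (bytes of every array)."""
    import hashlib

    h = hashlib.sha256()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name]).tobytes())
    return h.hexdigest()


def save_checkpoint(path: str | Path, model, config: dict | None = None) -> None:
    """Serialize a model's parameter map (.npz) plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config or {}, indent=2, default=str))


def load_checkpoint(path: str | Path, model) -> None:
    with np.load(Path(path), allow_pickle=False) as data:
        model.load_state({k: data[k] for k in data.files})


def load_pretrained(model, weights_path: str | Path, strict: bool = True):
    """Load parameters by name and shape from a saved checkpoint.

    In strict mode any missing/extra/shape-mismatched name raises
    :class:`LoadError` listing the offenders; otherwise the overlap is
    loaded and the mismatches are logged and left untouched.
    """
    import logging

    with np.load(Path(weights_path), allow_pickle=False) as data:
        incoming = {k: data[k] for k in data.files}
    current = model.state()
    mismatched = [
        k for k in incoming
        if k not in current or current[k].shape != incoming[k].shape
    ]
    missing = [k for k in current if k not in incoming]
    if strict and (mismatched or missing):
        raise LoadError(
            f"checkpoint mismatch: unloadable={sorted(mismatched)}, "
            f"missing={sorted(missing)}"
        )
    if mismatched or missing:
        logging.getLogger(__name__).warning(
            "partial weight load: skipped %d, missing %d",
            len(mismatched), len(missing),
        )
    loadable = {k: v for k, v in incoming.items() if k not in mismatched}
    merged = {**current, **loadable}
    model.load_state(merged)
    return model
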