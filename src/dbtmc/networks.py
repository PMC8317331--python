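"""Network architectures and ensemble strategies.

Two branches classify a microcalcification cluster as benign or malignant:

* a 2D ResNet34 reading the resized focus slice (single channel, the final
  fully connected layer maps 512 pooled features to 2 classes);
* an anisotropic 3D ResNet reading an N-slice slab.  Every 3D convolution
  is factorized into a k x k x 1 intra-slice kernel K1 followed by a
  1 x 1 x k inter-slice kernel K2, matching the anisotropic voxel grid
  (~0.1 mm in-plane vs 1 mm between slices).  For k=3 and equal channel
  counts the pair holds 4/9 of the weights of an isotropic k^3 kernel.

The branches are fused either at feature level (concatenate the two pooled
512-vectors, one linear layer to 2 logits) or at decision level (convex
combination of the two softmax probability vectors; the unweighted average
is weight 0.5).

Through-plane resolution is never strided away: with only 8–12 slices the
slice axis keeps its full depth through all residual blocks, and
downsampling ("feature map scaled to 1/2") happens in-plane only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Add,
    BatchNorm,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    InterSliceConv3d,
    IntraSliceConv3d,
    Linear,
    MaxPool2d,
    MaxPool3dInPlane,
    ReLU,
    Sequential,
    softmax,
)
from .nn.layers import Layer, Param

__all__ = [
    "AnisoConvSpec",
    "Aniso3dNetConfig",
    "EnsembleConfig",
    "Classifier",
    "aniso_conv_forward",
    "aniso_param_count",
    "isotropic_param_count",
    "build_aniso_resnet3d",
    "build_resnet34_2d",
    "FeatureEnsembleHead",
    "feature_ensemble_forward",
    "decision_ensemble",
]


# ---------------------------------------------------------------------------
# factorized anisotropic convolution
# ---------------------------------------------------------------------------


@dataclass
class AnisoConvSpec:
    """Specification of one factorized anisotropic 3D convolution.

    K1 is the k x k x 1 intra-slice kernel (c_in -> c_temp), K2 the
    1 x 1 x k inter-slice kernel (c_temp -> c_out), applied in that order.
    ``stride`` is (s_w, s_h, s_d); K1 takes the in-plane part, K2 the
    through-plane part.
    """

    k: int = 3
    c_in: int = 1
    c_temp: int = 1
    c_out: int = 1
    stride: tuple[int, int, int] = (1, 1, 1)
    k1: np.ndarray | None = None  # (c_temp, c_in, k, k)
    k2: np.ndarray | None = None  # (c_out, c_temp, k)

    def __post_init__(self) -> None:
        if min(self.c_in, self.c_temp, self.c_out) < 1:
            raise ValueError("channel counts must be positive")
        if self.k1 is not None and self.k1.shape != (self.c_temp, self.c_in, self.k, self.k):
            raise ValueError(f"K1 must have shape (c_temp, c_in, k, k), got {self.k1.shape}")
        if self.k2 is not None and self.k2.shape != (self.c_out, self.c_temp, self.k):
            raise ValueError(f"K2 must have shape (c_out, c_temp, k), got {self.k2.shape}")


def aniso_param_count(spec: AnisoConvSpec) -> int:
    """Weights in the factorized pair: k*k*c_in*c_temp + k*c_temp*c_out."""
    return spec.k * spec.k * spec.c_in * spec.c_temp + spec.k * spec.c_temp * spec.c_out


def isotropic_param_count(spec: AnisoConvSpec) -> int:
    """Weights of the equivalent unfactorized k x k x k kernel."""
    return spec.k**3 * spec.c_in * spec.c_out


class AnisoConv(Layer):
    """K1 (intra-slice) followed by K2 (inter-slice) as one layer."""

    def __init__(self, c_in, c_temp, c_out, k=3, stride=(1, 1, 1), rng=None):
        s_w, s_h, s_d = stride
        if s_w != s_h:
            raise ValueError("in-plane stride must be square")
        self.intra = IntraSliceConv3d(c_in, c_temp, k, s_w, rng=rng)
        self.inter = InterSliceConv3d(c_temp, c_out, k, s_d, rng=rng)

    def params(self):
        return self.intra.params() + self.inter.params()

    def forward(self, x, train=False):
        return self.inter.forward(self.intra.forward(x, train), train)

    def backward(self, dy):
        return self.intra.backward(self.inter.backward(dy))


def aniso_conv_forward(f_in: np.ndarray, spec: AnisoConvSpec) -> np.ndarray:
    """Apply a factorized anisotropic convolution to a (B, W, H, D, C) map.

    'Same' padding everywhere, so with unit stride the output spatial shape
    equals the input shape and only the channel count changes.
    """
    f_in = np.asarray(f_in)
    if f_in.ndim != 5:
        raise ValueError("expected a (B, W, H, D, C) feature map")
    if f_in.shape[-1] != spec.c_in:
        raise ValueError(f"expected {spec.c_in} channels, got {f_in.shape[-1]}")
    layer = AnisoConv(spec.c_in, spec.c_temp, spec.c_out, spec.k, spec.stride,
                      rng=np.random.default_rng(0))
    if spec.k1 is not None:
        layer.intra.conv.w.value = spec.k1.astype(np.float32)
    if spec.k2 is not None:
        layer.inter.conv.w.value = spec.k2[..., None].astype(np.float32)
    x = f_in.transpose(0, 4, 3, 2, 1)  # (B, C, D, H, W)
    y = layer.forward(x, train=False)
    return y.transpose(0, 4, 3, 2, 1)


# ---------------------------------------------------------------------------
# classifier container
# ---------------------------------------------------------------------------


class Classifier:
    """Trunk -> global average pool -> dropout -> linear logits.

    ``last_features`` retains the pooled feature vector of the most recent
    forward pass, which is what the feature-level ensemble concatenates.
    """

    def __init__(self, trunk: Sequential, feat_dim: int, n_classes: int,
                 dropout_p: float, seed: int):
        rng = np.random.default_rng(seed)
        self.trunk = trunk
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(dropout_p, seed=seed + 1)
        self.fc = Linear(feat_dim, n_classes, rng=rng)
        self.feat_dim = feat_dim
        self.n_classes = n_classes
        self.last_features: np.ndarray | None = None

    def params(self) -> list[Param]:
        return self.trunk.params() + self.fc.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.gap.forward(self.trunk.forward(x, train), train)
        self.last_features = f
        return self.fc.forward(self.dropout.forward(f, train), train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.dropout.backward(self.fc.backward(dlogits))
        return self.trunk.backward(self.gap.backward(d))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    # -- serialization ------------------------------------------------------

    def _batchnorms(self) -> list[BatchNorm]:
        found: list[BatchNorm] = []

        def walk(layer):
            if isinstance(layer, BatchNorm):
                found.append(layer)
            elif isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, Add):
                walk(layer.main)
                if layer.shortcut is not None:
                    walk(layer.shortcut)

        walk(self.trunk)
        return found

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            v = np.asarray(state[f"param_{i}"])
            if v.shape != p.value.shape:
                raise ValueError(f"shape mismatch for param_{i}")
            p.value = v.astype(np.float32)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float32)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


# ---------------------------------------------------------------------------
# 2D ResNet34 branch
# ---------------------------------------------------------------------------


def _module_2d(c_in, c_out, stride, rng) -> Sequential:
    main = Sequential([
        Conv2d(c_in, c_out, 3, stride, rng=rng),
        BatchNorm(c_out),
        ReLU(),
        Conv2d(c_out, c_out, 3, 1, rng=rng),
        BatchNorm(c_out),
    ])
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential([Conv2d(c_in, c_out, 1, stride, rng=rng),
                               BatchNorm(c_out)])
    return Sequential([Add(main, shortcut), ReLU()])


def build_resnet34_2d(
    n_classes: int = 2,
    in_channels: int = 1,
    block_modules: tuple[int, ...] = (3, 4, 6, 3),
    block_channels: tuple[int, ...] = (64, 128, 256, 512),
    dropout_p: float = 0.5,
    seed: int = 0,
) -> Classifier:
    """34-layer residual network adapted to single-channel input, 2 logits.

    Smaller ``block_modules`` / ``block_channels`` give reduced-width
    variants for desk-scale training; the defaults are the canonical
    (3, 4, 6, 3) x (64, 128, 256, 512) design.
    """
    if len(block_modules) != len(block_channels):
        raise ValueError("block_modules and block_channels must align")
    rng = np.random.default_rng(seed)
    stem_ch = block_channels[0]
    layers: list = [
        Conv2d(in_channels, stem_ch, 7, 2, rng=rng),
        BatchNorm(stem_ch),
        ReLU(),
        MaxPool2d(3, 2),
    ]
    c_prev = stem_ch
    for b, (n_mod, c_out) in enumerate(zip(block_modules, block_channels)):
        for m in range(n_mod):
            stride = 2 if (b > 0 and m == 0) else 1
            layers.append(_module_2d(c_prev, c_out, stride, rng))
            c_prev = c_out
    return Classifier(Sequential(layers), feat_dim=c_prev, n_classes=n_classes,
                      dropout_p=dropout_p, seed=seed)


# ---------------------------------------------------------------------------
# anisotropic 3D ResNet branch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Aniso3dNetConfig:
    """Architecture of the anisotropic 3D ResNet.

    The stem is a 7 x 7 x 1 convolution (64 channels, in-plane stride 2)
    followed by in-plane 3 x 3 x 1 max pooling; four residual blocks with
    (3, 4, 6, 3) modules output (64, 128, 256, 512) channels, each module
    holding four anisotropic convolutions (two K1/K2 pairs).  The slice
    axis is never strided.
    """

    stem_channels: int = 64
    stem_kernel: int = 7
    block_modules: tuple[int, ...] = (3, 4, 6, 3)
    block_channels: tuple[int, ...] = (64, 128, 256, 512)
    dropout_p: float = 0.5
    n_classes: int = 2
    in_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.block_modules) != len(self.block_channels):
            raise ValueError("block_modules and block_channels must align")
        if any(c2 < c1 for c1, c2 in zip(self.block_channels, self.block_channels[1:])):
            raise ValueError("block channels must be non-decreasing")

    @classmethod
    def desk(cls, **overrides) -> "Aniso3dNetConfig":
        """Reduced-width variant for CPU-scale training experiments."""
        base = dict(stem_channels=8, block_modules=(1, 1, 1, 1),
                    block_channels=(8, 16, 32, 64))
        base.update(overrides)
        return cls(**base)


def _module_aniso(c_in, c_out, stride_inplane, rng) -> Sequential:
    main = Sequential([
        IntraSliceConv3d(c_in, c_out, 3, stride_inplane, rng=rng),
        BatchNorm(c_out),
        ReLU(),
        InterSliceConv3d(c_out, c_out, 3, 1, rng=rng),
        BatchNorm(c_out),
        ReLU(),
        IntraSliceConv3d(c_out, c_out, 3, 1, rng=rng),
        BatchNorm(c_out),
        ReLU(),
        InterSliceConv3d(c_out, c_out, 3, 1, rng=rng),
        BatchNorm(c_out),
    ])
    shortcut = None
    if stride_inplane != 1 or c_in != c_out:
        shortcut = Sequential([
            IntraSliceConv3d(c_in, c_out, 1, stride_inplane, rng=rng),
            BatchNorm(c_out),
        ])
    return Sequential([Add(main, shortcut), ReLU()])


def build_aniso_resnet3d(cfg: Aniso3dNetConfig = Aniso3dNetConfig(),
                         seed: int = 0) -> Classifier:
    """Build the anisotropic 3D ResNet; input layout (B, 1, D, H, W)."""
    rng = np.random.default_rng(seed)
    layers: list = [
        IntraSliceConv3d(cfg.in_channels, cfg.stem_channels, cfg.stem_kernel, 2,
                         rng=rng),
        BatchNorm(cfg.stem_channels),
        ReLU(),
        MaxPool3dInPlane(3, 2),
    ]
    c_prev = cfg.stem_channels
    for b, (n_mod, c_out) in enumerate(zip(cfg.block_modules, cfg.block_channels)):
        for m in range(n_mod):
            stride = 2 if (b > 0 and m == 0) else 1
            layers.append(_module_aniso(c_prev, c_out, stride, rng))
            c_prev = c_out
    return Classifier(Sequential(layers), feat_dim=c_prev,
                      n_classes=cfg.n_classes, dropout_p=cfg.dropout_p, seed=seed)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleConfig:
    """mode 'feature' or 'decision'; weight_2d only applies to decision mode
    (0.5 is the unweighted average)."""

    mode: str = "decision"
    weight_2d: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("feature", "decision"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        if not 0.0 <= self.weight_2d <= 1.0:
            raise ValueError("weight_2d must lie in [0, 1]")


class FeatureEnsembleHead:
    """Single linear layer over the concatenated (2D, 3D) pooled features."""

    def __init__(self, feat_dim_2d: int = 512, feat_dim_3d: int = 512,
                 n_classes: int = 2, seed: int = 0):
        self.feat_dim_2d = feat_dim_2d
        self.feat_dim_3d = feat_dim_3d
        self.fc = Linear(feat_dim_2d + feat_dim_3d, n_classes,
                         rng=np.random.default_rng(seed))

    def params(self):
        return self.fc.params()

    def forward(self, feat2d: np.ndarray, feat3d: np.ndarray,
                train: bool = False) -> np.ndarray:
        return self.fc.forward(_concat_features(feat2d, feat3d,
                                                self.feat_dim_2d,
                                                self.feat_dim_3d), train)

    def backward(self, dlogits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = self.fc.backward(dlogits)
        return d[:, : self.feat_dim_2d], d[:, self.feat_dim_2d :]


def _concat_features(feat2d, feat3d, n2d, n3d) -> np.ndarray:
    feat2d = np.atleast_2d(np.asarray(feat2d))
    feat3d = np.atleast_2d(np.asarray(feat3d))
    if feat2d.shape[1] != n2d or feat3d.shape[1] != n3d:
        raise ValueError(
            f"feature length mismatch: got {feat2d.shape[1]} and "
            f"{feat3d.shape[1]}, expected {n2d} and {n3d}"
        )
    return np.concatenate([feat2d, feat3d], axis=1)  # order (2D, 3D), fixed


def feature_ensemble_forward(feat2d: np.ndarray, feat3d: np.ndarray,
                             head: FeatureEnsembleHead) -> np.ndarray:
    """Concatenate pooled feature vectors (2D first) and map to 2 logits."""
    return head.forward(feat2d, feat3d, train=False)


def decision_ensemble(p2d: np.ndarray, p3d: np.ndarray,
                      weight_2d: float = 0.5) -> np.ndarray:
    """Convex combination of the two branches' class probabilities.

    weight_2d = 0.5 is the unweighted average; the result is always a
    valid probability vector.
    """
    if not 0.0 <= weight_2d <= 1.0:
        raise ValueError("weight_2d must lie in [0, 1]")
    p2d = np.asarray(p2d, dtype=float)
    p3d = np.asarray(p3d, dtype=float)
    if p2d.shape != p3d.shape:
        raise ValueError("probability arrays must have matching shapes")
    for name, p in (("p2d", p2d), ("p3d", p3d)):
        if np.any(p < 0) or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError(f"{name} is not a valid probability vector")
    return weight_2d * p2d + (1.0 - weight_2d) * p3d
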