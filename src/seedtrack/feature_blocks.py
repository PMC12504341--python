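"""Forward-pass operators for the two detector-backbone modifications.

Two framework-free building blocks used to strengthen small-target feature
extraction in a YOLOv5s-class backbone:

* **SOCA** (second-order channel attention): channel reweighting driven by
  the inter-channel covariance matrix of the feature map, ``Z = sigmoid(W2
  relu(S) W1)`` applied as a per-channel scale.
* **SimSPPF** (simplified spatial pyramid pooling, fast): a ConvBNReLU
  followed by three iterated stride-1 max-pools whose outputs are
  concatenated channel-wise and fused by a second ConvBNReLU.

All operators are pure functions on ``numpy`` arrays shaped ``(C, H, W)``;
there is no autograd and no training here — parameters are inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOCAParams",
    "ConvBNReLUParams",
    "SimSPPFParams",
    "center_features",
    "channel_covariance",
    "soca_attention",
    "soca_forward",
    "max_pool_2d",
    "conv_bn_relu",
    "simsppf_forward",
    "load_soca_params",
    "load_simsppf_params",
]

_CENTER_TOL = 1e-9


def _validate_feature_map(x: np.ndarray, name: str = "X") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"{name} must be a (C, H, W) array, got shape {x.shape}")
    if x.size == 0:
        raise ValueError(f"{name} must have C*H*W >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x


@dataclass
class SOCAParams:
    """Learnable weights of the attention head: ``W1`` (C×1), ``W2`` (C×C)."""

    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.ndim != 2 or self.w1.shape[1] != 1:
            raise ValueError(f"W1 must be C x 1, got {self.w1.shape}")
        c = self.w1.shape[0]
        if self.w2.shape != (c, c):
            raise ValueError(f"W2 must be {c} x {c}, got {self.w2.shape}")
        if not (np.all(np.isfinite(self.w1)) and np.all(np.isfinite(self.w2))):
            raise ValueError("SOCA weights must be finite")

    @property
    def n_channels(self) -> int:
        return self.w1.shape[0]


@dataclass
class ConvBNReLUParams:
    """1x1 convolution + batch norm (inference statistics) + ReLU.

    ``weight`` has shape (C_out, C_in); batch-norm vectors have length C_out.
    """

    weight: np.ndarray
    bias: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if self.weight.ndim != 2:
            raise ValueError("conv weight must be (C_out, C_in)")
        c_out = self.weight.shape[0]
        for name in ("bias", "bn_mean", "bn_var", "bn_gamma", "bn_beta"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (c_out,):
                raise ValueError(f"{name} must have length {c_out}, got {v.shape}")
            setattr(self, name, v)

    @classmethod
    def identity(cls, channels: int) -> "ConvBNReLUParams":
        """Unit weights on the diagonal, zero bias, neutral batch norm."""
        return cls(
            weight=np.eye(channels),
            bias=np.zeros(channels),
            bn_mean=np.zeros(channels),
            bn_var=np.ones(channels),
            bn_gamma=np.ones(channels),
            bn_beta=np.zeros(channels),
            bn_eps=0.0,
        )

    @property
    def in_channels(self) -> int:
        return self.weight.shape[1]

    @property
    def out_channels(self) -> int:
        return self.weight.shape[0]


@dataclass
class SimSPPFParams:
    """Parameter bundle of the SimSPPF block.

    ``conv_out`` must accept ``4 * conv_in.out_channels`` channels: the
    direct branch plus three iterated pool outputs, concatenated.
    """

    conv_in: ConvBNReLUParams
    conv_out: ConvBNReLUParams
    pool_kernel: int = 5

    def __post_init__(self) -> None:
        if self.pool_kernel % 2 == 0 or self.pool_kernel < 1:
            raise ValueError("pool_kernel must be odd and positive")
        if self.conv_out.in_channels != 4 * self.conv_in.out_channels:
            raise ValueError(
                "conv_out input channels must equal 4 x conv_in output channels "
                f"({self.conv_out.in_channels} != 4*{self.conv_in.out_channels})"
            )


def center_features(x: np.ndarray) -> np.ndarray:
    """Subtract each channel's spatial mean (the map ``X̂``).

    Every output channel sums to zero, which is the precondition for the
    covariance computation.
    """
    x = _validate_feature_map(x)
    return x - x.mean(axis=(1, 2), keepdims=True)


def channel_covariance(xhat: np.ndarray) -> np.ndarray:
    """Inter-channel covariance ``S_ij = (1/HW) sum_hw X̂_i X̂_j``.

    Requires a mean-centered input; raises if any channel mean exceeds
    tolerance. The result is exactly symmetric and PSD up to roundoff.
    """
    xhat = _validate_feature_map(xhat, "Xhat")
    c, h, w = xhat.shape
    means = xhat.mean(axis=(1, 2))
    if np.any(np.abs(means) > _CENTER_TOL * max(h * w, 1) + 1e-12):
        raise ValueError("input to channel_covariance is not mean-centered")
    flat = xhat.reshape(c, h * w)
    s = flat @ flat.T / (h * w)
    return (s + s.T) / 2.0


def soca_attention(s: np.ndarray, params: SOCAParams) -> np.ndarray:
    """Attention weights ``Z = sigmoid(W2 relu(S) W1)``, a length-C vector.

    ``relu`` acts elementwise on the covariance matrix; every output entry
    lies strictly in (0, 1).
    """
    s = np.asarray(s, dtype=float)
    c = params.n_channels
    if s.shape != (c, c):
        raise ValueError(f"S must be {c} x {c}, got {s.shape}")
    pre = params.w2 @ np.maximum(s, 0.0) @ params.w1
    z = 1.0 / (1.0 + np.exp(-pre[:, 0]))
    # sigmoid saturates to exactly 0/1 in float64 around |x| ~ 37; clamp to
    # the open interval the contract promises
    return np.clip(z, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def soca_forward(x: np.ndarray, params: SOCAParams) -> np.ndarray:
    """Full SOCA pass: center -> covariance -> attention -> reweight.

    Output channel i is ``Z_i * X_i``; shape is preserved.
    """
    x = _validate_feature_map(x)
    if x.shape[0] != params.n_channels:
        raise ValueError(
            f"params built for C={params.n_channels}, feature map has C={x.shape[0]}"
        )
    z = soca_attention(channel_covariance(center_features(x)), params)
    return z[:, None, None] * x


def max_pool_2d(x: np.ndarray, kernel: int, stride: int = 1, pad: int | None = None) -> np.ndarray:
    """Stride-1 max pooling with -inf padding; spatial size preserved.

    ``pad`` defaults to ``(kernel - 1) // 2``, the symmetric padding that
    keeps H and W unchanged at stride 1.
    """
    x = _validate_feature_map(x)
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("kernel must be odd and positive")
    if stride != 1:
        raise ValueError("only stride 1 is supported")
    if pad is None:
        pad = (kernel - 1) // 2
    if pad != (kernel - 1) // 2:
        raise ValueError("pad must be (kernel - 1) // 2")
    c, h, w = x.shape
    padded = np.full((c, h + 2 * pad, w + 2 * pad), -np.inf)
    padded[:, pad : pad + h, pad : pad + w] = x
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kernel, kernel), axis=(1, 2))
    return windows.max(axis=(3, 4))


def conv_bn_relu(x: np.ndarray, p: ConvBNReLUParams) -> np.ndarray:
    """1x1 conv + inference-mode batch norm + ReLU on a (C, H, W) map."""
    x = _validate_feature_map(x)
    if x.shape[0] != p.in_channels:
        raise ValueError(f"conv expects {p.in_channels} channels, got {x.shape[0]}")
    y = np.tensordot(p.weight, x, axes=([1], [0])) + p.bias[:, None, None]
    scale = p.bn_gamma / np.sqrt(p.bn_var + p.bn_eps)
    y = scale[:, None, None] * (y - p.bn_mean[:, None, None]) + p.bn_beta[:, None, None]
    return np.maximum(y, 0.0)


def simsppf_forward(x: np.ndarray, params: SimSPPFParams) -> np.ndarray:
    """SimSPPF block: ConvBNReLU, three iterated max-pools, concat, ConvBNReLU.

    With pool kernel k at stride 1, the second and third pooled branches are
    equivalent to single pools with effective windows 2k-1 and 3k-2, giving
    the multi-scale receptive fields the block exists for.
    """
    y = conv_bn_relu(x, params.conv_in)
    p1 = max_pool_2d(y, params.pool_kernel)
    p2 = max_pool_2d(p1, params.pool_kernel)
    p3 = max_pool_2d(p2, params.pool_kernel)
    stacked = np.concatenate([y, p1, p2, p3], axis=0)
    return conv_bn_relu(stacked, params.conv_out)


# -- JSON (de)serialization: nested lists keep fixtures diffable ------------


def _conv_from_dict(d: dict) -> ConvBNReLUParams:
    return ConvBNReLUParams(
        weight=d["weight"],
        bias=d["bias"],
        bn_mean=d["bn_mean"],
        bn_var=d["bn_var"],
        bn_gamma=d["bn_gamma"],
        bn_beta=d["bn_beta"],
        bn_eps=float(d.get("bn_eps", 1e-5)),
    )


def load_soca_params(path_or_obj, expected_channels: int | None = None) -> SOCAParams:
    """Load SOCA weights from a JSON file (keys ``w1``, ``w2``)."""
    obj = _load_json(path_or_obj)
    params = SOCAParams(w1=obj["w1"], w2=obj["w2"])
    if expected_channels is not None and params.n_channels != expected_channels:
        raise ValueError(
            f"params declare C={params.n_channels}, expected C={expected_channels}"
        )
    return params


def load_simsppf_params(path_or_obj) -> SimSPPFParams:
    """Load SimSPPF parameters from JSON (keys ``conv_in``, ``conv_out``, ``pool_kernel``)."""
    obj = _load_json(path_or_obj)
    return SimSPPFParams(
        conv_in=_conv_from_dict(obj["conv_in"]),
        conv_out=_conv_from_dict(obj["conv_out"]),
        pool_kernel=int(obj.get("pool_kernel", 5)),
    )


def _load_json(path_or_obj):
    if isinstance(path_or_obj, dict):
        return path_or_obj
    with open(path_or_obj) as fh:
        return json.load(fh)
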