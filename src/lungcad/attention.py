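"""Convolutional block attention (CBAM) as pure tensor math.

Channel attention reweights feature channels using a shared two-layer MLP
applied to global average- and max-pooled descriptors; spatial attention
reweights locations using a convolution over the channel-wise average and
maximum maps.  Both gates pass through a sigmoid, so attention weights lie
strictly inside (0, 1) and the composed operator never amplifies a feature.
Weights are supplied by the caller (or drawn from a seeded initializer);
no training happens here — the operators exist to be composed with any
feature-extraction backbone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["CbamWeights", "channel_attention", "spatial_attention", "cbam",
           "save_weights", "load_weights"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CbamWeights:
    """Parameters of the channel MLP and the spatial convolution.

    ``w_down`` (C x C/r) and ``w_up`` (C/r x C) form the shared channel MLP
    with a ReLU between them; ``spatial_kernel`` is a k x k x 2 stencil
    applied to the stacked [channel-average, channel-max] maps, plus a
    scalar ``spatial_bias``.  ``r`` must divide C and ``k`` must be odd.
    """

    w_down: np.ndarray
    w_up: np.ndarray
    reduction: int
    spatial_kernel: np.ndarray
    spatial_bias: float = 0.0

    def __post_init__(self) -> None:
        self.w_down = np.asarray(self.w_down, dtype=float)
        self.w_up = np.asarray(self.w_up, dtype=float)
        self.spatial_kernel = np.asarray(self.spatial_kernel, dtype=float)
        c, hidden = self.w_down.shape
        if c % self.reduction != 0 or hidden != c // self.reduction:
            raise ValueError("w_down must be C x C/r with r dividing C")
        if self.w_up.shape != (hidden, c):
            raise ValueError("w_up must be C/r x C")
        k = self.spatial_kernel.shape[0]
        if self.spatial_kernel.shape != (k, k, 2) or k % 2 == 0:
            raise ValueError("spatial kernel must be k x k x 2 with odd k")

    @property
    def n_channels(self) -> int:
        return self.w_down.shape[0]

    @classmethod
    def random(cls, n_channels: int, reduction: int = 16, kernel_size: int = 7,
               rng: np.random.Generator | None = None) -> "CbamWeights":
        """He-scaled random weights for ``n_channels`` channels."""
        if n_channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide C={n_channels}")
        rng = np.random.default_rng() if rng is None else rng
        hidden = n_channels // reduction
        w_down = rng.normal(0, np.sqrt(2.0 / n_channels), (n_channels, hidden))
        w_up = rng.normal(0, np.sqrt(2.0 / max(hidden, 1)), (hidden, n_channels))
        kern = rng.normal(0, np.sqrt(2.0 / (2 * kernel_size**2)), (kernel_size, kernel_size, 2))
        return cls(w_down=w_down, w_up=w_up, reduction=reduction, spatial_kernel=kern)


def _check_input(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"expected C x H x W tensor, got shape {f.shape}")
    if f.shape[0] != w.n_channels:
        raise ValueError(f"feature map has {f.shape[0]} channels, weights expect {w.n_channels}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite entries")
    return f


def _channel_mlp(v: np.ndarray, w: CbamWeights) -> np.ndarray:
    return np.maximum(v @ w.w_down, 0.0) @ w.w_up


def channel_attention(f: np.ndarray, w: CbamWeights) -> tuple[np.ndarray, np.ndarray]:
    """Gate each channel by sigmoid(MLP(avgpool) + MLP(maxpool)).

    Pooling is global over the spatial extent.  Returns the reweighted
    tensor and the per-channel attention map.
    """
    f = _check_input(f, w)
    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))
    gate = _sigmoid(_channel_mlp(avg, w) + _channel_mlp(mx, w))
    return gate[:, None, None] * f, gate


def spatial_attention(f: np.ndarray, w: CbamWeights) -> tuple[np.ndarray, np.ndarray]:
    """Gate each location by a sigmoid convolution of [channel-avg; channel-max].

    The k x k x 2 kernel is cross-correlated with same-size zero padding, so
    output shape equals input shape.
    """
    f = _check_input(f, w)
    stacked = np.stack([f.mean(axis=0), f.max(axis=0)])  # 2 x H x W
    conv = sum(
        ndimage.correlate(stacked[i], w.spatial_kernel[:, :, i], mode="constant", cval=0.0)
        for i in range(2)
    )
    gate = _sigmoid(conv + w.spatial_bias)
    return gate[None, :, :] * f, gate


def cbam(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    """Serial channel-then-spatial attention; shape preserving."""
    f_c, _ = channel_attention(f, w)
    f_r, _ = spatial_attention(f_c, w)
    return f_r


# ---------------------------------------------------------------------------
# weight serialization: one flat float64 blob + a JSON sidecar with shapes

def save_weights(w: CbamWeights, path: str | Path) -> None:
    path = Path(path)
    blob = np.concatenate([w.w_down.ravel(), w.w_up.ravel(), w.spatial_kernel.ravel(),
                           [w.spatial_bias]]).astype("<f8")
    blob.tofile(path)
    meta = {
        "w_down": list(w.w_down.shape),
        "w_up": list(w.w_up.shape),
        "spatial_kernel": list(w.spatial_kernel.shape),
        "reduction": w.reduction,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_weights(path: str | Path) -> CbamWeights:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    blob = np.fromfile(path, dtype="<f8")
    sizes = [int(np.prod(meta[k])) for k in ("w_down", "w_up", "spatial_kernel")]
    parts = np.split(blob, np.cumsum(sizes))
    return CbamWeights(
        w_down=parts[0].reshape(meta["w_down"]),
        w_up=parts[1].reshape(meta["w_up"]),
        reduction=meta["reduction"],
        spatial_kernel=parts[2].reshape(meta["spatial_kernel"]),
        spatial_bias=float(parts[3][0]),
    )
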