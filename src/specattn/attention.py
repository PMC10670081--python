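"""Channel, spectral, and joint attention transforms for 1-D feature maps.

A feature map is ``channels x length`` (unbatched) or ``batch x channels x
length``.  The channel attention module (CAM) gates whole channels using
pooled channel statistics pushed through a shared two-layer 1x1-conv
bottleneck; the spectral attention module (SAM) gates individual positions
(bands) using a channel-collapsing 1x1 convolution; the joint module (CSAM)
applies SAM first, then CAM.  All three are residual: the input is added
back to its gated copy.

Functions accept plain numpy arrays (pure forward transforms) or autodiff
:class:`~specattn.engine.Tensor` inputs/parameters (used inside the
trainable network), via the dispatch helpers in :mod:`specattn.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Tensor, amax, amean, asum, relu, reshape, sigmoid

__all__ = [
    "CamParams",
    "SamParams",
    "channel_pool",
    "cam_weights",
    "cam_forward",
    "sam_weights",
    "sam_forward",
    "csam_forward",
]

CAM_GATES = ("literal", "post_sum")


def _n_channels(y) -> int:
    shape = y.shape
    if len(shape) not in (2, 3):
        raise ValueError(f"feature map must be 2-D or 3-D (got shape {shape})")
    return shape[-2]


@dataclass
class CamParams:
    """Shared bottleneck parameters for channel attention.

    ``reduce_*`` is the channel-squeezing 1x1 conv (f1), ``expand_*`` the
    channel-restoring one (f2); both are shared between the max-pool and
    average-pool branches.
    """

    reduce_weights: np.ndarray          # (channels/r, channels)
    reduce_bias: np.ndarray             # (channels/r,)
    expand_weights: np.ndarray          # (channels, channels/r)
    expand_bias: np.ndarray             # (channels,)
    reduction_ratio: int = 4

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")

    @property
    def channels(self) -> int:
        return int(np.asarray(self.reduce_weights.data if isinstance(self.reduce_weights, Tensor)
                              else self.reduce_weights).shape[1])

    @classmethod
    def initialize(cls, channels: int, reduction_ratio: int = 4,
                   rng: np.random.Generator | None = None) -> "CamParams":
        """He-initialized weights, zero biases.  Non-divisible ``channels``
        round the bottleneck width up (ceil)."""
        rng = rng or np.random.default_rng()
        hidden = max(1, -(-channels // reduction_ratio))
        w1 = rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels))
        w2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(channels, hidden))
        return cls(w1, np.zeros(hidden), w2, np.zeros(channels), reduction_ratio)


@dataclass
class SamParams:
    """Channel-collapsing 1x1 conv for spectral attention."""

    weights: np.ndarray                 # (channels,)
    bias: float | np.ndarray = 0.0

    @property
    def channels(self) -> int:
        return int(np.asarray(self.weights.data if isinstance(self.weights, Tensor)
                              else self.weights).shape[-1])

    @classmethod
    def initialize(cls, channels: int,
                   rng: np.random.Generator | None = None) -> "SamParams":
        # near-identity start: T* ~ 0 so the residual gate barely perturbs
        # early training, like zero-init residual branches in ResNets
        rng = rng or np.random.default_rng()
        return cls(rng.normal(0.0, 0.05 / np.sqrt(channels), size=channels), 0.0)


def channel_pool(y):
    """Global average and max pooling over the length axis.

    Returns ``(z_avg, z_max)``, each shaped like the feature map with the
    length axis removed: ``(channels,)`` for 2-D input, ``(batch, channels)``
    for 3-D.
    """
    _n_channels(y)
    return amean(y, axis=-1), amax(y, axis=-1)


def _swap(w):
    """Transpose a 2-D weight matrix (Tensor-aware)."""
    if isinstance(w, Tensor):
        def bw(out):
            def run():
                if w.requires_grad:
                    w._accum(out.grad.T)
            return run
        return Tensor._result(w.data.T, (w,), bw)
    return np.asarray(w).T


def _bottleneck(z, p: CamParams):
    """f2(ReLU(f1(z))) for z of shape (..., channels); returns pre-gate logits."""
    c = p.channels
    lead = z.shape[:-1]
    z2 = reshape(z, (-1, c))
    h = relu(z2 @ _swap(p.reduce_weights) + p.reduce_bias)
    out = h @ _swap(p.expand_weights) + p.expand_bias
    return reshape(out, lead + (c,))


def cam_weights(y, p: CamParams, gate: str = "literal"):
    """Per-channel gate vector Z*.

    ``gate='literal'`` applies the sigmoid per pooled branch and sums the two
    gated branches (range (0, 2)); ``gate='post_sum'`` sums the branch logits
    first and applies one sigmoid (range (0, 1))."""
    if gate not in CAM_GATES:
        raise ValueError(f"gate must be one of {CAM_GATES}, got {gate!r}")
    c = _n_channels(y)
    if c != p.channels:
        raise ValueError(f"channel mismatch: feature map has {c}, CamParams expect {p.channels}")
    z_avg, z_max = channel_pool(y)
    if gate == "literal":
        return sigmoid(_bottleneck(z_max, p)) + sigmoid(_bottleneck(z_avg, p))
    return sigmoid(_bottleneck(z_max, p) + _bottleneck(z_avg, p))


def cam_forward(y, p: CamParams, gate: str = "literal"):
    """Residual channel attention: ``Y + Y * Z*`` with Z* broadcast along length."""
    z_star = cam_weights(y, p, gate=gate)
    z_b = reshape(z_star, z_star.shape + (1,))
    return y + y * z_b


def sam_weights(y, p: SamParams):
    """Per-position gate vector T* = ReLU(w . y_j + b), one value per band."""
    c = _n_channels(y)
    if c != p.channels:
        raise ValueError(f"channel mismatch: feature map has {c}, SamParams expect {p.channels}")
    w_col = reshape(p.weights, (c, 1))
    return relu(asum(y * w_col, axis=-2) + p.bias)


def sam_forward(y, p: SamParams):
    """Residual spectral attention: ``Y + T* * Y`` with T* broadcast across channels."""
    t_star = sam_weights(y, p)
    t_b = reshape(t_star, t_star.shape[:-1] + (1, t_star.shape[-1]))
    return y + t_b * y


def csam_forward(y, cam: CamParams, sam: SamParams, gate: str = "literal"):
    """Joint attention: SAM first, then CAM."""
    return cam_forward(sam_forward(y, sam), cam, gate=gate)
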