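"""The attention-enhanced 1-D CNN: six batch-normalized conv/pool blocks,
optional attention insertions, a four-layer fully connected head, and a
softmax output.

The reference stack (for a 288-band input) uses kernels (9,7,5,3,3,3),
channels (16,16,32,64,64,32), stride-1 same-padded convolutions and halving
max pools, compressing 288 bands to a 32 x 4 feature map; the FC head is
(64, 32, 16, n_classes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import attention as attn
from . import engine
from .engine import Tensor, no_grad

__all__ = [
    "ConvBlockSpec",
    "ArchitectureSpec",
    "ATTENTION_MODES",
    "build_architecture",
    "shape_chain",
    "init_params",
    "conv_block_forward",
    "fully_connected_forward",
    "softmax",
    "model_forward",
    "Model",
    "save_checkpoint",
    "load_checkpoint",
]

ATTENTION_MODES = ("none", "cam", "sam", "csam")

DEFAULT_KERNELS = (9, 7, 5, 3, 3, 3)
DEFAULT_CHANNELS = (16, 16, 32, 64, 64, 32)
DEFAULT_FC_HIDDEN = (64, 32, 16)
# attention rows sit after the first four conv/pool blocks by default; a
# five-placement variant adds one after the fifth block
DEFAULT_ATTENTION_BLOCKS = (0, 1, 2, 3)
FIVE_ATTENTION_BLOCKS = (0, 1, 2, 3, 4)

CHECKPOINT_SCHEMA = 1


@dataclass
class ConvBlockSpec:
    kernel_size: int
    in_channels: int
    out_channels: int
    conv_stride: int = 1
    padded: bool = True
    pool: str = "max"                    # {max, avg, none}
    pool_kernel: int = 2
    pool_stride: int = 2
    batch_norm_before: bool = True
    attention_after: str = "none"        # {none, cam, sam, csam}

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1 (same-padding requires odd)")
        if self.conv_stride < 1 or self.pool_stride < 1:
            raise ValueError("strides must be >= 1")
        if self.pool not in ("max", "avg", "none"):
            raise ValueError("pool must be one of max/avg/none")
        if self.attention_after not in ATTENTION_MODES:
            raise ValueError(f"attention_after must be one of {ATTENTION_MODES}")


@dataclass
class ArchitectureSpec:
    input_bands: int
    blocks: list[ConvBlockSpec]
    fc_sizes: list[int]
    n_classes: int
    dropout_rate: float = 0.3
    cam_reduction: int = 4
    cam_gate: str = "literal"            # {literal, post_sum}

    def __post_init__(self):
        if self.fc_sizes[-1] != self.n_classes:
            raise ValueError("last FC size must equal n_classes")
        if self.input_bands < 16:
            raise ValueError("input_bands must be >= 16")
        if self.cam_gate not in attn.CAM_GATES:
            raise ValueError(f"cam_gate must be one of {attn.CAM_GATES}")


def build_architecture(n_bands: int, n_classes: int, attention_mode: str = "none",
                       attention_placements: tuple[int, ...] | None = None,
                       dropout_rate: float = 0.3, cam_reduction: int = 4,
                       cam_gate: str = "literal") -> ArchitectureSpec:
    """Assemble the six-block reference architecture for ``n_bands`` input.

    ``attention_mode`` selects what to insert after the blocks listed in
    ``attention_placements`` (default: the first four blocks).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if attention_mode not in ATTENTION_MODES:
        raise ValueError(f"attention_mode must be one of {ATTENTION_MODES}")
    placements = tuple(attention_placements) if attention_placements is not None \
        else (DEFAULT_ATTENTION_BLOCKS if attention_mode != "none" else ())
    blocks = []
    in_ch = 1
    for i, (k, ch) in enumerate(zip(DEFAULT_KERNELS, DEFAULT_CHANNELS)):
        after = attention_mode if (attention_mode != "none" and i in placements) else "none"
        blocks.append(ConvBlockSpec(kernel_size=k, in_channels=in_ch, out_channels=ch,
                                    attention_after=after))
        in_ch = ch
    spec = ArchitectureSpec(input_bands=n_bands, blocks=blocks,
                            fc_sizes=list(DEFAULT_FC_HIDDEN) + [n_classes],
                            n_classes=n_classes, dropout_rate=dropout_rate,
                            cam_reduction=cam_reduction, cam_gate=cam_gate)
    shape_chain(spec)   # raises if the pooling chain exhausts the signal
    return spec


def shape_chain(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """(channels, length) after each conv/pool block; validates feasibility."""
    length = spec.input_bands
    chain = []
    for i, blk in enumerate(spec.blocks):
        if not blk.padded:
            length = length - blk.kernel_size + 1
        length = length // blk.conv_stride if blk.conv_stride > 1 else length
        if blk.pool != "none":
            length = length // blk.pool_kernel
        if length < 1:
            raise ValueError(
                f"input of {spec.input_bands} bands is exhausted at block {i + 1}: "
                "too few bands to survive the pooling chain")
        chain.append((blk.out_channels, length))
    return chain


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def init_params(spec: ArchitectureSpec,
                rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """He-initialized weights, zero biases, unit BN scale, fresh running stats."""
    rng = rng or np.random.default_rng()
    P: dict[str, np.ndarray] = {}
    for i, blk in enumerate(spec.blocks):
        p = f"block{i}"
        if blk.batch_norm_before:
            P[f"{p}.bn.gamma"] = np.ones(blk.in_channels)
            P[f"{p}.bn.beta"] = np.zeros(blk.in_channels)
            P[f"{p}.bn.running_mean"] = np.zeros(blk.in_channels)
            P[f"{p}.bn.running_var"] = np.ones(blk.in_channels)
        fan_in = blk.in_channels * blk.kernel_size
        P[f"{p}.conv.w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(blk.out_channels, blk.in_channels,
                                            blk.kernel_size))
        P[f"{p}.conv.b"] = np.zeros(blk.out_channels)
        if blk.attention_after in ("cam", "csam"):
            cam = attn.CamParams.initialize(blk.out_channels, spec.cam_reduction, rng)
            P[f"{p}.cam.w1"] = cam.reduce_weights
            P[f"{p}.cam.b1"] = cam.reduce_bias
            P[f"{p}.cam.w2"] = cam.expand_weights
            P[f"{p}.cam.b2"] = cam.expand_bias
        if blk.attention_after in ("sam", "csam"):
            sam = attn.SamParams.initialize(blk.out_channels, rng)
            P[f"{p}.sam.w"] = sam.weights
            P[f"{p}.sam.b"] = np.zeros(())
    final_ch, final_len = shape_chain(spec)[-1]
    in_size = final_ch * final_len
    for j, out_size in enumerate(spec.fc_sizes):
        P[f"fc{j}.w"] = rng.normal(0.0, np.sqrt(2.0 / in_size), size=(in_size, out_size))
        P[f"fc{j}.b"] = np.zeros(out_size)
        in_size = out_size
    return P


def _is_trainable(name: str) -> bool:
    return "running" not in name


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _apply_block(blk: ConvBlockSpec, get, x: Tensor, training: bool,
                 spec: ArchitectureSpec) -> Tensor:
    if blk.batch_norm_before:
        x = engine.batch_norm1d(x, get("bn.gamma"), get("bn.beta"),
                                get("bn.running_mean", raw=True),
                                get("bn.running_var", raw=True), training)
    pad = (blk.kernel_size - 1) // 2 if blk.padded else 0
    x = engine.conv1d(x, get("conv.w"), get("conv.b"), padding=pad).relu()
    if blk.pool == "max":
        x = engine.max_pool1d(x, blk.pool_kernel, blk.pool_stride)
    elif blk.pool == "avg":
        x = engine.avg_pool1d(x, blk.pool_kernel, blk.pool_stride)
    mode = blk.attention_after
    if mode != "none":
        cam = attn.CamParams(get("cam.w1"), get("cam.b1"), get("cam.w2"), get("cam.b2"),
                             spec.cam_reduction) if mode in ("cam", "csam") else None
        sam = attn.SamParams(get("sam.w"), get("sam.b")) if mode in ("sam", "csam") else None
        if mode == "cam":
            x = attn.cam_forward(x, cam, gate=spec.cam_gate)
        elif mode == "sam":
            x = attn.sam_forward(x, sam)
        elif mode == "csam":
            x = attn.csam_forward(x, cam, sam, gate=spec.cam_gate)
    return x


def _getter(params: dict, prefix: str, wrap: dict | None):
    """Parameter accessor; ``wrap`` maps names to Tensors when training."""
    def get(key: str, raw: bool = False):
        name = f"{prefix}{key}"
        if raw or wrap is None:
            return params[name]
        return wrap[name]
    return get


def _forward(spec: ArchitectureSpec, params: dict, tensors: dict | None,
             x: Tensor, training: bool = False,
             drop_rng: np.random.Generator | None = None) -> Tensor:
    """Shared forward pass; ``x`` is a (N, 1, bands) Tensor, returns logits."""
    for i, blk in enumerate(spec.blocks):
        x = _apply_block(blk, _getter(params, f"block{i}.", tensors), x, training, spec)
    n = x.shape[0]
    x = x.reshape((n, x.shape[1] * x.shape[2]))
    last = len(spec.fc_sizes) - 1
    for j in range(len(spec.fc_sizes)):
        get = _getter(params, f"fc{j}.", tensors)
        x = x @ get("w") + get("b")
        if j < last:
            x = x.relu()
            if training and spec.dropout_rate > 0:
                x = engine.dropout(x, spec.dropout_rate, drop_rng)
    return x


def conv_block_forward(block: ConvBlockSpec, params: dict, X: np.ndarray,
                       cam_reduction: int = 4, cam_gate: str = "literal") -> np.ndarray:
    """Run one block on an unbatched (channels x length) feature map, eval mode.

    ``params`` uses local names: ``bn.gamma``, ``bn.beta``, ``bn.running_mean``,
    ``bn.running_var``, ``conv.w``, ``conv.b``, and attention entries
    ``cam.w1/b1/w2/b2`` / ``sam.w/b`` as applicable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D channels x length feature map")
    if X.shape[0] != block.in_channels:
        raise ValueError(f"feature map has {X.shape[0]} channels, block expects "
                         f"{block.in_channels}")
    dummy = ArchitectureSpec(input_bands=max(16, X.shape[1]), blocks=[block],
                             fc_sizes=[2], n_classes=2, cam_reduction=cam_reduction,
                             cam_gate=cam_gate)
    with no_grad():
        out = _apply_block(block, _getter(params, "", None), Tensor(X[None]),
                           training=False, spec=dummy)
    return out.data[0] if isinstance(out, Tensor) else np.asarray(out)[0]


def fully_connected_forward(sizes: list[int], params: dict, v: np.ndarray,
                            dropout_rate: float = 0.0, training: bool = False,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Affine + ReLU chain (final layer affine only); returns logits.

    ``params`` holds ``fc{j}.w`` of shape (in, out) and ``fc{j}.b``.
    Dropout only applies in training mode, after hidden activations.
    """
    v = np.asarray(v, dtype=float)
    squeeze = v.ndim == 1
    x = Tensor(v[None] if squeeze else v)
    if x.shape[1] != params["fc0.w"].shape[0]:
        raise ValueError(f"input size {x.shape[1]} does not match fc0 weight "
                         f"{params['fc0.w'].shape}")
    last = len(sizes) - 1
    with no_grad():
        for j in range(len(sizes)):
            x = x @ Tensor(params[f"fc{j}.w"]) + Tensor(params[f"fc{j}.b"])
            if j < last:
                x = x.relu()
                if training and dropout_rate > 0:
                    x = engine.dropout(x, dropout_rate, rng or np.random.default_rng())
    out = x.data
    return out[0] if squeeze else out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("softmax requires finite logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def model_forward(spec: ArchitectureSpec, params: dict, X: np.ndarray) -> np.ndarray:
    """Full eval-mode pass: (n_samples, bands) spectra -> class probabilities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.input_bands:
        lens = {288: "SWIR", 108: "VNIR"}.get(spec.input_bands, f"{spec.input_bands}-band")
        raise ValueError(
            f"spectra have {X.shape[1]} bands but this architecture expects "
            f"{spec.input_bands} (the {lens} lens)")
    with no_grad():
        logits = _forward(spec, params, None, Tensor(X[:, None, :]), training=False)
    return softmax(logits.data)


# ---------------------------------------------------------------------------
# trainable model wrapper
# ---------------------------------------------------------------------------

class Model:
    """Holds an architecture plus parameters; supports training and inference."""

    def __init__(self, spec: ArchitectureSpec,
                 params: dict[str, np.ndarray] | None = None, seed: int = 0):
        self.spec = spec
        arrays = params if params is not None else init_params(
            spec, np.random.default_rng(seed))
        # raw arrays (running stats mutate in place); trainable ones wrapped once
        self.params: dict[str, np.ndarray] = {k: np.array(v, dtype=engine.DTYPE)
                                              for k, v in arrays.items()}
        self.tensors: dict[str, Tensor] = {
            k: Tensor(self.params[k], requires_grad=True)
            for k in self.params if _is_trainable(k)}
        for k, t in self.tensors.items():     # share storage with params dict
            self.params[k] = t.data

    def trainable(self) -> list[Tensor]:
        return list(self.tensors.values())

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        X = np.asarray(X)
        return _forward(self.spec, self.params, self.tensors,
                        Tensor(X[:, None, :]), training=training, drop_rng=rng)

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        with no_grad():
            for s in range(0, X.shape[0], batch_size):
                logits = self.forward(X[s:s + batch_size], training=False)
                out.append(softmax(logits.data))
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def export_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, spec: ArchitectureSpec,
                    params: dict[str, np.ndarray]) -> None:
    """Single-file container: versioned architecture JSON + named arrays."""
    meta = {"schema": CHECKPOINT_SCHEMA, "arch": asdict(spec)}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **params)


def load_checkpoint(path: str) -> tuple[ArchitectureSpec, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')!r}")
        arch = meta["arch"]
        blocks = [ConvBlockSpec(**b) for b in arch.pop("blocks")]
        spec = ArchitectureSpec(blocks=blocks, **arch)
        params = {k: z[k] for k in z.files if k != "__meta__"}
    return spec, params
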