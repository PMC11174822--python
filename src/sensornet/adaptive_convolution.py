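"""Cross-channel patch-wise self-attention with convolution-generated heads.

The trunk stacks three *attention iterations*.  Each iteration

1. projects its input into query/key/value head tensors with 1x1
   convolutions over the head axis (a double-layer expansion at the first
   iteration where there is only a single head to start from),
2. unfolds every head's per-channel map into attention-kernel patches,
3. computes, per head and patch group, a cross-channel attention matrix
   ``A[i, j] = softmax_j( sigmoid(q_i) . k_j )`` and aggregates values over
   the key channels,
4. folds patches back to maps and adaptively average-pools.

All head-axis convolutions share their weights across the sensor channels, so
the trunk's parameter count is independent of the number of input channels C
and one trained trunk runs unchanged on inputs with a different C.  The final
iteration permutes channels against heads and pools (C, H, W) to (1, 1, 1),
producing one scalar per head regardless of C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Module, uniform_param
from .patching import PatchTensor, count_patch_groups

__all__ = [
    "HeadTensor",
    "AttentionWeights",
    "IterationConfig",
    "HeadExpansionFirst",
    "HeadMix",
    "StandardHeadMix",
    "QKVProjection",
    "AttentionIteration",
    "expand_heads_first",
    "mix_heads",
    "project_qkv",
    "attention_weights",
    "attend",
    "adaptive_pool",
    "run_iteration",
    "standard_multihead",
]

_ROLES = {"input", "query", "key", "value", "attended", "pooled"}


@dataclass(frozen=True)
class HeadTensor:
    """Per-channel multi-head feature maps, shape (C, M, H, W)."""

    values: np.ndarray
    role: str = "input"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 4:
            raise ValueError(f"HeadTensor values must be (C, M, H, W), got {v.shape}")
        if v.shape[1] < 1:
            raise ValueError("need at least one head")
        if not np.all(np.isfinite(v)):
            raise ValueError("HeadTensor contains non-finite values")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_heads(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AttentionWeights:
    """Normalised cross-channel scores per patch group, shape (C, C, B).

    Index ``[i, j, b]``: weight of key channel j for query channel i in
    group b; rows over j sum to one.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"weights must be (C, C, B), got {v.shape}")


@dataclass(frozen=True)
class IterationConfig:
    out_heads: int
    pool_target: tuple[int, int, int] | None
    kernel: tuple[int, int] = (2, 2)
    stride: int = 2
    squeeze_channels: bool = False

    def __post_init__(self):
        if self.out_heads < 1:
            raise ValueError("out_heads must be >= 1")
        if self.pool_target is not None and any(d < 1 for d in self.pool_target):
            raise ValueError("pool target dims must be >= 1")


# ---------------------------------------------------------------------------
# head-axis 1x1 convolutions (the "dense layer")
# ---------------------------------------------------------------------------

class HeadExpansionFirst(Module):
    """Double-layer 1x1 convolution expanding a single head to ``out_heads``.

    Layer 1 applies one scalar filter per output head (1 -> M); layer 2
    linearly recombines across the M heads (M groups of 1x1xM filters).
    Weights are shared across the channel axis C.
    """

    def __init__(self, out_heads: int, rng: np.random.Generator):
        if out_heads < 1:
            raise ValueError("out_heads must be >= 1")
        self.out_heads = out_heads
        self.w1 = uniform_param(rng, (out_heads,), 1)
        self.b1 = uniform_param(rng, (out_heads,), 1)
        self.w2 = uniform_param(rng, (out_heads, out_heads), out_heads)
        self.b2 = uniform_param(rng, (out_heads,), out_heads)

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, C, 1, H, W)
        if x.shape[2] != 1:
            raise ValueError(f"first-iteration expansion requires M=1, got M={x.shape[2]}")
        n, c, _, h, w = x.shape
        flat = ad.reshape(x, (n, c, h, w))
        h1 = ad.add(ad.einsum("nchw,m->ncmhw", flat, self.w1),
                    ad.reshape(self.b1, (1, 1, -1, 1, 1)))
        h2 = ad.add(ad.einsum("ncmhw,om->ncohw", h1, self.w2),
                    ad.reshape(self.b2, (1, 1, -1, 1, 1)))
        return h2


class HeadMix(Module):
    """Single 1x1xM convolution over the head axis, M -> out_heads.

    ``out_heads=1`` realises the summarised single head; larger values
    generate new multi-head subspaces.  Shared across channels.
    """

    def __init__(self, in_heads: int, out_heads: int, rng: np.random.Generator):
        if out_heads < 1:
            raise ValueError("out_heads must be >= 1")
        self.in_heads = in_heads
        self.out_heads = out_heads
        self.weight = uniform_param(rng, (out_heads, in_heads), in_heads)
        self.bias = uniform_param(rng, (out_heads,), in_heads)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.in_heads:
            raise ValueError(f"expected M={self.in_heads}, got {x.shape[2]}")
        return ad.add(ad.einsum("ncmhw,om->ncohw", x, self.weight),
                      ad.reshape(self.bias, (1, 1, -1, 1, 1)))


class StandardHeadMix(Module):
    """Comparator head aggregation: per-position fully connected mixing.

    Unlike :class:`HeadMix`, the M -> out_heads weights are *not* shared
    across spatial positions, i.e. every (h, w) owns its own mixing matrix,
    which is what makes the fully connected variant so much larger.
    """

    def __init__(self, map_size: tuple[int, int], in_heads: int, out_heads: int,
                 rng: np.random.Generator):
        self.map_size = tuple(map_size)
        self.in_heads = in_heads
        self.out_heads = out_heads
        h, w = self.map_size
        self.weight = uniform_param(rng, (h, w, out_heads, in_heads), in_heads)
        self.bias = uniform_param(rng, (h, w, out_heads), in_heads)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.in_heads or tuple(x.shape[-2:]) != self.map_size:
            raise ValueError(
                f"expected (*, *, {self.in_heads}, {self.map_size[0]}, {self.map_size[1]}), "
                f"got {tuple(x.shape)}"
            )
        y = ad.einsum("ncmhw,hwom->ncohw", x, self.weight)
        return ad.add(y, ad.transpose(ad.reshape(self.bias, (1, 1) + self.bias.shape),
                                      (0, 1, 4, 2, 3)))


class QKVProjection(Module):
    """Three independently parameterised head projections (query/key/value)."""

    def __init__(self, in_heads: int, out_heads: int, first_iteration: bool,
                 rng: np.random.Generator, mode: str = "conv",
                 map_size: tuple[int, int] | None = None):
        if mode not in ("conv", "standard"):
            raise ValueError(f"unknown multihead mode {mode!r}")
        self.first_iteration = first_iteration

        def make():
            if first_iteration:
                return HeadExpansionFirst(out_heads, rng)
            if mode == "standard":
                return StandardHeadMix(map_size, in_heads, out_heads, rng)
            return HeadMix(in_heads, out_heads, rng)

        self.query = make()
        self.key = make()
        self.value = make()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        return self.query(x), self.key(x), self.value(x)


# ---------------------------------------------------------------------------
# attention core
# ---------------------------------------------------------------------------

def _attention_scores(qp: Tensor, kp: Tensor) -> Tensor:
    """(N, C, M, P, B) q/k patches -> normalised (N, M, C, C, B) weights."""
    scores = ad.einsum("nimpb,njmpb->nmijb", ad.sigmoid(qp), kp)
    return ad.softmax(scores, axis=3)


def _attention_apply(weights: Tensor, vp: Tensor) -> Tensor:
    """Aggregate value patches over key channels: (N, C, M, P, B) out."""
    return ad.einsum("nmijb,njmpb->nimpb", weights, vp)


def _attention_block(q: Tensor, k: Tensor, v: Tensor,
                     kernel: tuple[int, int], stride: int) -> Tensor:
    """Patch-wise cross-channel attention on (N, C, M, H, W) head tensors."""
    h, w = q.shape[-2:]
    qp = ad.extract_patches_op(q, kernel, stride)
    kp = ad.extract_patches_op(k, kernel, stride)
    vp = ad.extract_patches_op(v, kernel, stride)
    weights = _attention_scores(qp, kp)
    attended = _attention_apply(weights, vp)
    return ad.fold_patches_op(attended, kernel, stride, (h, w))


def _pool_mhw(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    for axis, size in zip((2, 3, 4), target):
        x = ad.adaptive_avg_pool_axis(x, axis, size)
    return x


class AttentionIteration(Module):
    """One dense-layer + attention-layer iteration of the trunk."""

    def __init__(self, in_heads: int, cfg: IterationConfig, first: bool,
                 rng: np.random.Generator, mode: str = "conv",
                 map_size: tuple[int, int] | None = None):
        self.cfg = cfg
        self.projection = QKVProjection(in_heads, cfg.out_heads, first, rng,
                                        mode=mode, map_size=map_size)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        q, k, v = self.projection(x)
        folded = _attention_block(q, k, v, cfg.kernel, cfg.stride)
        if cfg.squeeze_channels:
            # (N, C, M, H, W) -> (N, M, C, H, W), then global-average the
            # channel and spatial axes: one scalar per head, any C.
            permuted = ad.transpose(folded, (0, 2, 1, 3, 4))
            return _pool_mhw(permuted, (1, 1, 1))
        return _pool_mhw(folded, cfg.pool_target)


# ---------------------------------------------------------------------------
# functional surface (single-sample, numpy in / numpy out)
# ---------------------------------------------------------------------------

def _to_batched(x: HeadTensor) -> Tensor:
    return Tensor(x.values[None, ...])


def expand_heads_first(input: HeadTensor, out_heads: int, *,
                       module: HeadExpansionFirst | None = None,
                       rng: np.random.Generator | None = None) -> HeadTensor:
    """Expand an M=1 head tensor to ``out_heads`` via the double-layer block."""
    if module is None:
        module = HeadExpansionFirst(out_heads, rng or np.random.default_rng(0))
    out = module(_to_batched(input))
    return HeadTensor(out.data[0], role="input")


def mix_heads(input: HeadTensor, out_heads: int, *,
              module: HeadMix | None = None,
              rng: np.random.Generator | None = None) -> HeadTensor:
    """Mix M heads into ``out_heads`` with a single 1x1xM convolution."""
    if module is None:
        module = HeadMix(input.n_heads, out_heads, rng or np.random.default_rng(0))
    out = module(_to_batched(input))
    return HeadTensor(out.data[0], role="input")


def project_qkv(input: HeadTensor, out_heads: int, first_iteration: bool, *,
                module: QKVProjection | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[HeadTensor, HeadTensor, HeadTensor]:
    """Project into query, key, value head tensors."""
    if module is None:
        module = QKVProjection(input.n_heads, out_heads, first_iteration,
                               rng or np.random.default_rng(0))
    q, k, v = module(_to_batched(input))
    return (HeadTensor(q.data[0], role="query"),
            HeadTensor(k.data[0], role="key"),
            HeadTensor(v.data[0], role="value"))


def attention_weights(q_patches: PatchTensor, k_patches: PatchTensor) -> AttentionWeights:
    """Cross-channel attention scores for one head.

    ``A[i, j, b] = softmax_j( sigmoid(q_i)_b . (k_j)_b )`` with the dot
    product over the patch axis and the sigmoid applied to the query only.
    """
    if q_patches.values.shape != k_patches.values.shape:
        raise ValueError(
            f"query/key patch shapes differ: {q_patches.values.shape} vs "
            f"{k_patches.values.shape}"
        )
    qp = Tensor(q_patches.values[None, :, None, :, :])
    kp = Tensor(k_patches.values[None, :, None, :, :])
    return AttentionWeights(_attention_scores(qp, kp).data[0, 0])


def attend(weights: AttentionWeights, v_patches: PatchTensor) -> PatchTensor:
    """Aggregate value patches with the given cross-channel weights."""
    c, _, b = weights.values.shape
    if v_patches.values.shape[0] != c or v_patches.values.shape[2] != b:
        raise ValueError(
            f"weights (C={c}, B={b}) do not match value patches "
            f"{v_patches.values.shape}"
        )
    w = Tensor(weights.values[None, None])
    vp = Tensor(v_patches.values[None, :, None, :, :])
    out = _attention_apply(w, vp).data[0, :, 0]
    return PatchTensor(out, v_patches.kernel, v_patches.stride, v_patches.source_size)


def adaptive_pool(input: HeadTensor, pool_target: tuple[int, int, int],
                  squeeze_channels: bool = False) -> HeadTensor:
    """Adaptive average pooling over (M, H, W) — or (C, H, W) when squeezing.

    With ``squeeze_channels`` the tensor is first permuted C x M x H x W ->
    M x C x H x W and pooled to (1, 1, 1), summarising each head into a
    single channel-independent scalar.
    """
    x = _to_batched(input)
    if squeeze_channels:
        x = ad.transpose(x, (0, 2, 1, 3, 4))
        out = _pool_mhw(x, (1, 1, 1))
    else:
        out = _pool_mhw(x, pool_target)
    return HeadTensor(out.data[0], role="pooled")


def run_iteration(input: HeadTensor, cfg: IterationConfig, first: bool = False, *,
                  module: AttentionIteration | None = None,
                  rng: np.random.Generator | None = None) -> HeadTensor:
    """Run one full iteration (projection, attention, fold, pool)."""
    if module is None:
        module = AttentionIteration(input.n_heads, cfg, first,
                                    rng or np.random.default_rng(0))
    out = module(_to_batched(input))
    return HeadTensor(out.data[0], role="pooled")


def standard_multihead(heads: HeadTensor, out_heads: int | None = None, *,
                       module: StandardHeadMix | None = None,
                       rng: np.random.Generator | None = None) -> HeadTensor:
    """Comparator path: per-position fully connected head aggregation."""
    if module is None:
        h, w = heads.values.shape[-2:]
        module = StandardHeadMix((h, w), heads.n_heads,
                                 out_heads or heads.n_heads,
                                 rng or np.random.default_rng(0))
    out = module(_to_batched(heads))
    return HeadTensor(out.data[0], role="input")


def patch_group_count_for(cfg: IterationConfig, map_size: tuple[int, int]) -> int:
    """Convenience: B for an iteration's geometry."""
    return count_patch_groups(map_size, cfg.kernel, cfg.stride)
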