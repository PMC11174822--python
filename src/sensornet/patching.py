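"""Sliding attention-kernel patch algebra.

A *patch* is a small window (the attention kernel, default 2x2) slid across a
spectrogram; every sliding position is a *patch group*.  Extraction unfolds a
``C x H x W`` map into ``C x Patch_Size x B`` (group order and within-patch
order both row-major); folding reverses it, averaging positions covered by
more than one window when the stride is smaller than the kernel.  With
stride equal to the kernel side (the default), folding is the exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchTensor",
    "count_patch_groups",
    "extract_patches",
    "fold_patches",
]


def _check_geometry(size: tuple[int, int], kernel: tuple[int, int], stride: int) -> None:
    h, w = size
    kh, kw = kernel
    if kh < 1 or kw < 1:
        raise ValueError(f"kernel must be positive, got {kernel}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if kh > h or kw > w:
        raise ValueError(f"kernel {kernel} larger than spectrogram {size}")


def count_patch_groups(spec_size: tuple[int, int], kernel: tuple[int, int],
                       stride: int) -> int:
    """Number of sliding-window positions B for the given geometry.

    ``B = prod_d floor((size[d] - (kernel[d]-1) - 1)/stride + 1)``; windows
    that do not fit are dropped (no padding).
    """
    _check_geometry(spec_size, kernel, stride)
    b = 1
    for d in range(2):
        b *= (spec_size[d] - (kernel[d] - 1) - 1) // stride + 1
    return b


@dataclass(frozen=True)
class PatchTensor:
    """Patch-unfolded view of per-channel maps.

    values : (C, Patch_Size, B) with Patch_Size = kh*kw.
    """

    values: np.ndarray
    kernel: tuple[int, int]
    stride: int
    source_size: tuple[int, int]

    def __post_init__(self):
        kh, kw = self.kernel
        if self.values.ndim != 3:
            raise ValueError("PatchTensor values must be (C, Patch_Size, B)")
        if self.values.shape[1] != kh * kw:
            raise ValueError(
                f"Patch_Size {self.values.shape[1]} != kernel product {kh * kw}"
            )
        expected_b = count_patch_groups(self.source_size, self.kernel, self.stride)
        if self.values.shape[2] != expected_b:
            raise ValueError(
                f"B={self.values.shape[2]} inconsistent with geometry (expected {expected_b})"
            )

    @property
    def patch_size(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return self.values.shape[2]


# -- pure numpy kernels (shared with the autodiff wrappers) -----------------

def _extract(x: np.ndarray, kernel: tuple[int, int], stride: int) -> np.ndarray:
    """(..., H, W) -> (..., kh*kw, B); both orders row-major."""
    kh, kw = kernel
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(-2, -1))
    win = win[..., ::stride, ::stride, :, :]  # (..., nH, nW, kh, kw)
    nh, nw = win.shape[-4], win.shape[-3]
    lead = win.shape[:-4]
    win = win.reshape(lead + (nh * nw, kh * kw))
    return np.ascontiguousarray(np.swapaxes(win, -1, -2))


def _scatter_add(patches: np.ndarray, kernel: tuple[int, int], stride: int,
                 size: tuple[int, int]) -> np.ndarray:
    """Adjoint of `_extract`: sum patch entries back onto the (H, W) grid."""
    kh, kw = kernel
    h, w = size
    nh = (h - kh) // stride + 1
    nw = (w - kw) // stride + 1
    lead = patches.shape[:-2]
    p = patches.reshape(lead + (kh, kw, nh, nw))
    out = np.zeros(lead + (h, w), dtype=patches.dtype)
    for di in range(kh):
        for dj in range(kw):
            out[..., di:di + nh * stride:stride, dj:dj + nw * stride:stride] += p[..., di, dj, :, :]
    return out


def _overlap_counts(size: tuple[int, int], kernel: tuple[int, int],
                    stride: int) -> np.ndarray:
    kh, kw = kernel
    nh = (size[0] - kh) // stride + 1
    nw = (size[1] - kw) // stride + 1
    ones = np.ones((kh * kw, nh * nw))
    counts = _scatter_add(ones, kernel, stride, size)
    counts[counts == 0] = 1.0  # uncovered cells (kernel does not tile the map)
    return counts


# -- public API -------------------------------------------------------------

def extract_patches(maps: np.ndarray, kernel: tuple[int, int],
                    stride: int) -> PatchTensor:
    """Unfold ``C x H x W`` maps into a :class:`PatchTensor`."""
    maps = np.asarray(maps)
    if maps.ndim != 3:
        raise ValueError(f"maps must be (C, H, W), got shape {maps.shape}")
    h, w = maps.shape[1:]
    _check_geometry((h, w), kernel, stride)
    return PatchTensor(_extract(maps, kernel, stride), kernel, stride, (h, w))


def fold_patches(patches: PatchTensor) -> np.ndarray:
    """Fold a :class:`PatchTensor` back to ``C x H x W``.

    Exact inverse of :func:`extract_patches` when stride equals the kernel
    side; with overlapping windows each position gets the mean contribution.
    """
    counts = _overlap_counts(patches.source_size, patches.kernel, patches.stride)
    return _scatter_add(patches.values, patches.kernel, patches.stride,
                        patches.source_size) / counts
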