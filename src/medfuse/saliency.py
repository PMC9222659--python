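"""Visual-saliency feature fusion and the simple baseline rules.

The fusion rule weights encoder features by how salient the CT activity is.
Saliency of a pixel is the sum of its absolute intensity differences to every
other pixel, which depends only on the intensity histogram and is therefore
computable in O(P + L) with prefix sums over the L gray levels instead of the
naive O(P * L) per-pixel scan.

The weight chain for the CT stack is

    l1 activity -> min-max normalise -> quantise -> saliency -> min-max

yielding a per-pixel weight map ``w1`` in [0, 1] shared across channels.
The fused stack is then, per channel,

    F = gamma * w1 * F_ct  +  (1 - gamma) * w1 * F_mri  +  (1 - w1) * F_mri

so the dense-structure term is a gamma-blend of both modalities and the
soft-tissue remainder comes from MRI alone; the three coefficients sum to 1
at every pixel.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .imgio import quantize_levels

__all__ = [
    "FusionParams",
    "l1_activity",
    "minmax_normalize",
    "vsm",
    "vsm_bruteforce",
    "ct_weight_map",
    "fuse_features",
    "fuse_baseline",
    "BASELINE_STRATEGIES",
]

BASELINE_STRATEGIES = ("avg", "max", "sum", "l1norm")


@dataclasses.dataclass(frozen=True)
class FusionParams:
    """Knobs of the fusion rule.

    gamma
        CT share inside the dense-structure term, in [0, 1].  Default 0.5
        (an even split; the method itself does not pin this down).
    levels
        Histogram resolution of the saliency transform (256 for 8-bit data).
    strategy
        ``"vsm"`` for the saliency rule or one of the element-wise baselines.
    mri_coefficient
        ``"convex"`` uses (1 - gamma) * w1 for the MRI part of the dense term
        so per-pixel coefficients sum to one; ``"literal"`` uses
        (1 - gamma * w1) instead.
    """

    gamma: float = 0.5
    levels: int = 256
    strategy: str = "vsm"
    mri_coefficient: str = "convex"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.strategy not in ("vsm",) + BASELINE_STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.mri_coefficient not in ("convex", "literal"):
            raise ValueError("mri_coefficient must be 'convex' or 'literal'")


def _as_stack(features: np.ndarray) -> np.ndarray:
    f = np.asarray(features, dtype=np.float64)
    if f.ndim == 2:
        f = f[:, :, None]
    if f.ndim != 3 or f.shape[2] < 1:
        raise ValueError(f"expected an H x W x C feature stack, got shape {f.shape}")
    return f


def l1_activity(features: np.ndarray) -> np.ndarray:
    """Per-pixel channel-wise l1 norm of a feature stack (activity map)."""
    return np.abs(_as_stack(features)).sum(axis=2)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affinely map a finite 2-D map onto [0, 1]; constant maps become zeros."""
    v = np.asarray(values, dtype=np.float64)
    if not np.isfinite(v).all():
        raise ValueError("map contains non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def vsm(levels_image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram visual saliency: pixel value v gets sum_m count(m)*|v - m|.

    Exact integer arithmetic; for level v with cumulative pixel count C(v)
    and cumulative intensity-weighted count S(v),

        f(v) = v*C(v) - S(v) + (S_total - S(v)) - v*(C_total - C(v)).
    """
    img = np.asarray(levels_image)
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("vsm expects an integer level image; quantise first")
    if img.min() < 0 or img.max() > levels - 1:
        raise ValueError(f"levels must lie in [0, {levels - 1}]")
    counts = np.bincount(img.ravel(), minlength=levels).astype(np.int64)
    grid = np.arange(levels, dtype=np.int64)
    csum = np.cumsum(counts)
    wsum = np.cumsum(counts * grid)
    total_c, total_w = csum[-1], wsum[-1]
    table = grid * csum - wsum + (total_w - wsum) - grid * (total_c - csum)
    return table[img]


def vsm_bruteforce(levels_image: np.ndarray, levels: int = 256) -> np.ndarray:
    """O(P * L) reference implementation of :func:`vsm` (oracle for tests)."""
    img = np.asarray(levels_image, dtype=np.int64)
    counts = np.bincount(img.ravel(), minlength=levels)
    out = np.zeros_like(img)
    for m in range(levels):
        out += counts[m] * np.abs(img - m)
    return out


def ct_weight_map(f_ct: np.ndarray, params: FusionParams = FusionParams()) -> np.ndarray:
    """Per-pixel fusion weight from CT encoder features, in [0, 1].

    The saliency output is re-normalised to [0, 1] so the downstream
    combination stays convex; a spatially constant stack yields the all-zero
    map (no pixel is salient).
    """
    activity = l1_activity(f_ct)
    norm = minmax_normalize(activity)
    quantised = quantize_levels(norm, params.levels)
    saliency = vsm(quantised, params.levels)
    return minmax_normalize(saliency.astype(np.float64))


def fuse_features(
    f_ct: np.ndarray,
    f_mri: np.ndarray,
    w1: np.ndarray,
    gamma: float = 0.5,
    mri_coefficient: str = "convex",
) -> np.ndarray:
    """Combine two feature stacks under the saliency weight map ``w1``."""
    a, b = _as_stack(f_ct), _as_stack(f_mri)
    if a.shape != b.shape:
        raise ValueError(f"stack shapes differ: {a.shape} vs {b.shape}")
    w = np.asarray(w1, dtype=np.float64)
    if w.shape != a.shape[:2]:
        raise ValueError(f"weight map shape {w.shape} != spatial shape {a.shape[:2]}")
    w = w[:, :, None]
    if mri_coefficient == "convex":
        dense = gamma * w * a + (1.0 - gamma) * w * b
    elif mri_coefficient == "literal":
        dense = gamma * w * a + (1.0 - gamma * w) * b
    else:
        raise ValueError("mri_coefficient must be 'convex' or 'literal'")
    soft = (1.0 - w) * b
    return dense + soft


def fuse_baseline(f_ct: np.ndarray, f_mri: np.ndarray, strategy: str) -> np.ndarray:
    """Element-wise baseline rules: avg, max, sum, and per-pixel l1-norm softmax."""
    a, b = _as_stack(f_ct), _as_stack(f_mri)
    if a.shape != b.shape:
        raise ValueError(f"stack shapes differ: {a.shape} vs {b.shape}")
    if strategy == "avg":
        return (a + b) / 2.0
    if strategy == "max":
        return np.maximum(a, b)
    if strategy == "sum":
        return a + b
    if strategy == "l1norm":
        na, nb = l1_activity(a), l1_activity(b)
        denom = na + nb
        wa = np.where(denom > 0, na / np.where(denom > 0, denom, 1.0), 0.5)
        return wa[:, :, None] * a + (1.0 - wa)[:, :, None] * b
    raise ValueError(f"unknown baseline strategy {strategy!r}")
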