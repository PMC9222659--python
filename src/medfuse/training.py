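"""Encoder-decoder reconstruction training with a mixed pixel + gradient loss.

During training the fusion stage is removed entirely: the network learns to
reproduce each source image from its own encoding (I -> I), with CT and MRI
images pooled into one training set since a single shared encoder serves both
modalities.  The loss is

    L = (1 / WH) * ( mu * ||I_out - I_in||_2^2  +  phi * ||grad I_out - grad I_in||_2^2 )

where the gradient operator is a 3x3 Sobel pair (horizontal + vertical,
reflect boundary), the pixel term carries energy/detail and the gradient term
carries structure.  Optimisation is Adam; every source of randomness (weight
init, shuffling) is derived from the config seed so CPU runs are bit
reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.metrics import peak_signal_noise_ratio

from . import _autodiff as ad
from ._autodiff import Tensor
from .imgio import GrayImage
from .network import (
    NetConfig,
    NetWeights,
    as_tensors,
    decode,
    decode_forward,
    encode,
    encode_forward,
    init_weights,
    save_weights,
)

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "TrainingDivergence",
    "mixed_loss",
    "train",
    "reconstruction_quality",
    "PSNR_CAP",
]

#: Sentinel reported when reconstruction is exact (PSNR would be infinite).
PSNR_CAP = 99.0

# Sobel derivative kernels, cross-correlation convention, derivative along
# rows (vertical) and columns (horizontal).
_SOBEL_V = np.outer([-1.0, 0.0, 1.0], [1.0, 2.0, 1.0])
_SOBEL_H = _SOBEL_V.T
# forward difference expressed as a centred 3-tap [0, -1, 1] so both gradient
# operators share the same (reflect-padded) convolution path
_FDIFF_V = np.outer([0.0, -1.0, 1.0], [0.0, 1.0, 0.0])
_FDIFF_H = _FDIFF_V.T


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; ``mu`` and ``phi`` balance pixel vs gradient loss."""

    mu: float = 1.0
    phi: float = 1.0
    lr: float = 1e-4
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0
    optimizer: str = "Adam"
    checkpoint_every: int = 0
    grad_op: str = "sobel"

    def __post_init__(self) -> None:
        if self.mu < 0 or self.phi < 0 or self.mu + self.phi <= 0:
            raise ValueError("mu, phi must be >= 0 with mu + phi > 0")
        if self.optimizer != "Adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.grad_op not in ("sobel", "forward_diff"):
            raise ValueError("grad_op must be 'sobel' or 'forward_diff'")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    """Total loss and its unweighted components: total = mu*pixel + phi*gradient."""

    total: float
    pixel_term: float
    gradient_term: float


def _grad_kernels(grad_op: str) -> tuple[np.ndarray, np.ndarray]:
    if grad_op == "sobel":
        return _SOBEL_V, _SOBEL_H
    return _FDIFF_V, _FDIFF_H


def _as_array(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D images, got shape {arr.shape}")
    return arr


def mixed_loss(
    output,
    target,
    mu: float = 1.0,
    phi: float = 1.0,
    grad_op: str = "sobel",
) -> LossBreakdown:
    """Evaluate the reconstruction loss between two images (or image batches).

    ``pixel_term`` is the per-pixel mean squared intensity difference;
    ``gradient_term`` is the per-pixel squared norm of the difference of the
    two stacked directional responses.  Both are averaged over a batch.
    """
    def norm(x) -> np.ndarray:
        arr = x.pixels if isinstance(x, GrayImage) else np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError(f"expected (H, W) or (N, H, W) images, got {arr.shape}")
        return arr

    out, tgt = norm(output), norm(target)
    if out.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {out.shape} vs {tgt.shape}")
    diff = out - tgt
    kv, kh = _grad_kernels(grad_op)
    pixel = float(np.mean(diff**2))
    gv = np.stack([ndimage.correlate(d, kv, mode="mirror") for d in diff])
    gh = np.stack([ndimage.correlate(d, kh, mode="mirror") for d in diff])
    gradient = float(np.mean(gv**2) + np.mean(gh**2))
    return LossBreakdown(
        total=mu * pixel + phi * gradient,
        pixel_term=pixel,
        gradient_term=gradient,
    )


def _loss_graph(
    out: Tensor, target: Tensor, mu: float, phi: float, kv: Tensor, kh: Tensor
) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable counterpart of :func:`mixed_loss` on (N, H, W, 1) tensors."""
    diff = out - target
    pixel = (diff * diff).mean()
    gv = ad.conv2d(diff, kv, padding="reflect")
    gh = ad.conv2d(diff, kh, padding="reflect")
    gradient = (gv * gv).mean() + (gh * gh).mean()
    return mu * pixel + phi * gradient, pixel, gradient


class _Adam:
    def __init__(self, tensors: dict[str, Tensor], lr: float):
        self.tensors = tensors
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in tensors.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in tensors.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, tensor in self.tensors.items():
            g = tensor.grad
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            tensor.data -= (self.lr * update).astype(tensor.data.dtype)
            tensor.grad = None


def train(
    dataset: Sequence,
    cfg: TrainConfig,
    net_cfg: NetConfig = NetConfig(),
    out_dir: str | Path | None = None,
    log=None,
) -> tuple[NetWeights, list[LossBreakdown]]:
    """Train the encoder-decoder on single images (fusion block removed).

    ``dataset`` is a flat sequence of images (both modalities pooled); each is
    its own reconstruction target.  Returns the trained weights and the
    per-epoch mean loss history.  Fully seeded: identical configs give
    identical histories on CPU.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    images = [_as_array(img) for img in dataset]
    shape = images[0].shape
    if any(img.shape != shape for img in images):
        raise ValueError("all training images must share one shape")

    weights = init_weights(net_cfg, cfg.seed)
    tensors = as_tensors(weights, trainable=True)
    dtype = net_cfg.np_dtype
    kv, kh = _grad_kernels(cfg.grad_op)
    kv_t = Tensor(kv.astype(dtype)[:, :, None, None])
    kh_t = Tensor(kh.astype(dtype)[:, :, None, None])
    stack = np.stack(images).astype(dtype)[..., None]
    optimizer = _Adam(tensors, cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[LossBreakdown] = []

    out_dir = Path(out_dir) if out_dir is not None else None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(images))
        totals = np.zeros(3)
        n_seen = 0
        for start in range(0, len(images), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            x = Tensor(stack[batch_idx])
            out = decode_forward(encode_forward(x, tensors, net_cfg), tensors, net_cfg)
            loss, pixel, gradient = _loss_graph(out, x, cfg.mu, cfg.phi, kv_t, kh_t)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergence(
                    f"non-finite loss {value} at epoch {epoch}, step {start}"
                )
            loss.backward()
            optimizer.step()
            n = len(batch_idx)
            totals += n * np.array([value, float(pixel.data), float(gradient.data)])
            n_seen += n
        epoch_loss = LossBreakdown(*(totals / n_seen))
        history.append(epoch_loss)
        weights.epochs = epoch + 1
        if log is not None:
            log(
                f"epoch={epoch + 1} mean_loss={epoch_loss.total:.6g} "
                f"pixel_term={epoch_loss.pixel_term:.6g} "
                f"gradient_term={epoch_loss.gradient_term:.6g}"
            )
        if out_dir is not None and cfg.checkpoint_every > 0:
            if (epoch + 1) % cfg.checkpoint_every == 0 or epoch + 1 == cfg.epochs:
                out_dir.mkdir(parents=True, exist_ok=True)
                save_weights(weights, out_dir / f"checkpoint_epoch{epoch + 1:04d}.npz")
    return weights, history


def reconstruction_quality(weights: NetWeights, heldout: Sequence) -> float:
    """Mean PSNR (dB) of decode(encode(image)) over held-out images.

    Exact reconstructions (infinite PSNR) are reported as ``PSNR_CAP``.
    """
    if len(heldout) == 0:
        raise ValueError("heldout must be nonempty")
    values = []
    for img in heldout:
        arr = _as_array(img)
        rec = decode(encode(arr, weights), weights, clip=True)
        if np.allclose(arr, rec, atol=0.0):
            values.append(PSNR_CAP)
            continue
        psnr = peak_signal_noise_ratio(arr, rec, data_range=1.0)
        values.append(min(float(psnr), PSNR_CAP))
    return float(np.mean(values))
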