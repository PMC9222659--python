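"""Siamese multi-scale encoder with mixed attention, and the reconstruction decoder.

The encoder is two stages applied to a single-channel image:

* **Multi-scale convolution block** — a shallow 3x3 conv followed by four
  parallel branches of two 3x3 convs each.  In the dense variant (default)
  the second conv of branch *i* sees the concatenation of every earlier
  branch's second-conv output with its own first-conv output; the plain
  variant concatenates only the immediately preceding branch.  The four
  branch outputs are concatenated and merged by a 1x1 conv.
* **Mixed attention block** — channel attention (global max+avg pooled
  descriptors through one shared bottleneck, summed, sigmoid) and spatial
  attention (per-pixel channel max+avg maps through a 7x7 conv, sigmoid)
  applied in parallel to the same input and merged by a 1x1 conv.

The decoder is five 3x3 convs narrowing to one channel, ReLU on the first
four layers only.  All convolutions are stride 1 and zero-padded so every
stage preserves the spatial size of the source image.  Both modalities are
encoded by the *same* weights (siamese contract).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .imgio import GrayImage

__all__ = [
    "NetConfig",
    "NetWeights",
    "init_weights",
    "save_weights",
    "load_weights",
    "mc_block",
    "channel_attention",
    "spatial_attention",
    "ma_block",
    "encode",
    "decode",
]


@dataclasses.dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters of the encoder-decoder."""

    shallow_channels: int = 60
    branch_channels: int = 60
    n_branches: int = 4
    encoder_out_channels: int = 240
    reduction: int = 16
    sa_kernel: int = 7
    decoder_channels: tuple[int, ...] = (240, 128, 64, 32, 16)
    dense_variant: str = "res2db"
    integrate_activation: str = "relu"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_branches != 4:
            raise ValueError("the encoder is defined with exactly four branches")
        if self.encoder_out_channels != self.n_branches * self.branch_channels:
            raise ValueError(
                "encoder_out_channels must equal n_branches * branch_channels"
            )
        if self.encoder_out_channels % self.reduction != 0:
            raise ValueError("encoder_out_channels must be divisible by reduction")
        if self.sa_kernel % 2 == 0 or self.sa_kernel < 1:
            raise ValueError("sa_kernel must be odd and positive")
        if len(self.decoder_channels) != 5:
            raise ValueError("the decoder has exactly five convolution layers")
        if self.decoder_channels[0] != self.encoder_out_channels:
            raise ValueError("decoder input width must match encoder output width")
        if self.dense_variant not in ("res2b", "res2db"):
            raise ValueError("dense_variant must be 'res2b' or 'res2db'")
        if self.integrate_activation not in ("relu", "linear"):
            raise ValueError("integrate_activation must be 'relu' or 'linear'")

    @classmethod
    def small(cls) -> "NetConfig":
        """Narrow profile for CPU-scale experiments (same topology)."""
        return cls(
            shallow_channels=8,
            branch_channels=8,
            encoder_out_channels=32,
            reduction=8,
            decoder_channels=(32, 16, 8, 8, 4),
        )

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _branch2_in_channels(cfg: NetConfig, i: int) -> int:
    """Input width of branch i's (1-based) second conv."""
    if i == 1:
        return cfg.branch_channels
    if cfg.dense_variant == "res2db":
        return i * cfg.branch_channels
    return 2 * cfg.branch_channels  # res2b: previous branch output + own first conv


def _layer_shapes(cfg: NetConfig) -> dict[str, tuple[int, ...]]:
    b, e = cfg.branch_channels, cfg.encoder_out_channels
    shapes: dict[str, tuple[int, ...]] = {
        "shallow": (3, 3, 1, cfg.shallow_channels),
    }
    for i in range(1, cfg.n_branches + 1):
        shapes[f"branch{i}_conv1"] = (3, 3, cfg.shallow_channels, b)
        shapes[f"branch{i}_conv2"] = (3, 3, _branch2_in_channels(cfg, i), b)
    shapes["integrate"] = (1, 1, cfg.n_branches * b, e)
    shapes["ca_reduce"] = (1, 1, e, e // cfg.reduction)
    shapes["ca_expand"] = (1, 1, e // cfg.reduction, e)
    shapes["sa_conv"] = (cfg.sa_kernel, cfg.sa_kernel, 2, 1)
    shapes["ma_integrate"] = (1, 1, 2 * e, e)
    widths = list(cfg.decoder_channels) + [1]
    for k in range(5):
        shapes[f"dec{k + 1}"] = (3, 3, widths[k], widths[k + 1])
    return shapes


@dataclasses.dataclass
class NetWeights:
    """All convolution kernels/biases keyed by layer name, plus metadata."""

    params: dict[str, np.ndarray]
    config: NetConfig
    seed: int
    epochs: int = 0

    def validate(self) -> None:
        expected = _layer_shapes(self.config)
        for name, shape in expected.items():
            if name not in self.params or f"{name}_b" not in self.params:
                raise ValueError(f"missing parameters for layer {name!r}")
            if self.params[name].shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {self.params[name].shape}, "
                    f"expected {shape}"
                )


def init_weights(cfg: NetConfig = NetConfig(), seed: int = 0) -> NetWeights:
    """Kaiming fan-in initialisation of every conv layer; biases start at zero."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, shape in _layer_shapes(cfg).items():
        fan_in = shape[0] * shape[1] * shape[2]
        std = np.sqrt(2.0 / fan_in)
        params[name] = rng.normal(0.0, std, shape).astype(cfg.np_dtype)
        params[f"{name}_b"] = np.zeros(shape[3], dtype=cfg.np_dtype)
    return NetWeights(params=params, config=cfg, seed=seed)


def save_weights(weights: NetWeights, path: str | Path) -> None:
    meta = {
        "config": dataclasses.asdict(weights.config),
        "seed": weights.seed,
        "epochs": weights.epochs,
    }
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
             **weights.params)


def load_weights(path: str | Path) -> NetWeights:
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["decoder_channels"] = tuple(cfg_dict["decoder_channels"])
    weights = NetWeights(
        params=params,
        config=NetConfig(**cfg_dict),
        seed=meta["seed"],
        epochs=meta["epochs"],
    )
    weights.validate()
    return weights


# -- forward passes on the autodiff tape -------------------------------------


def _conv(x: Tensor, p: dict[str, Tensor], name: str) -> Tensor:
    return ad.conv2d(x, p[name], p[f"{name}_b"])


def mc_forward(x: Tensor, p: dict[str, Tensor], cfg: NetConfig) -> Tensor:
    if x.data.ndim != 4 or x.data.shape[3] != 1:
        raise ValueError(f"expected (N, H, W, 1) input, got {x.data.shape}")
    f_in = ad.relu(_conv(x, p, "shallow"))
    first = [ad.relu(_conv(f_in, p, f"branch{i}_conv1")) for i in range(1, 5)]
    second: list[Tensor] = []
    for i in range(1, 5):
        if i == 1:
            inp = first[0]
        elif cfg.dense_variant == "res2db":
            inp = ad.concat(second + [first[i - 1]])
        else:
            inp = ad.concat([second[-1], first[i - 1]])
        second.append(ad.relu(_conv(inp, p, f"branch{i}_conv2")))
    merged = _conv(ad.concat(second), p, "integrate")
    if cfg.integrate_activation == "relu":
        merged = ad.relu(merged)
    return merged


def ca_forward(x: Tensor, p: dict[str, Tensor], cfg: NetConfig) -> Tensor:
    if x.data.shape[3] != cfg.encoder_out_channels:
        raise ValueError(
            f"channel attention expects {cfg.encoder_out_channels} channels, "
            f"got {x.data.shape[3]}"
        )

    def excite(v: Tensor) -> Tensor:
        return _conv(ad.relu(_conv(v, p, "ca_reduce")), p, "ca_expand")

    gate = ad.sigmoid(excite(ad.spatial_max_pool(x)) + excite(ad.spatial_avg_pool(x)))
    return x * gate


def sa_forward(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    pooled = ad.concat([ad.channel_max_pool(x), ad.channel_avg_pool(x)])
    gate = ad.sigmoid(_conv(pooled, p, "sa_conv"))
    return x * gate


def ma_forward(x: Tensor, p: dict[str, Tensor], cfg: NetConfig) -> Tensor:
    refined = ad.concat([ca_forward(x, p, cfg), sa_forward(x, p)])
    return _conv(refined, p, "ma_integrate")


def encode_forward(x: Tensor, p: dict[str, Tensor], cfg: NetConfig) -> Tensor:
    return ma_forward(mc_forward(x, p, cfg), p, cfg)


def decode_forward(f: Tensor, p: dict[str, Tensor], cfg: NetConfig) -> Tensor:
    if f.data.shape[3] != cfg.decoder_channels[0]:
        raise ValueError(
            f"decoder expects {cfg.decoder_channels[0]} channels, got {f.data.shape[3]}"
        )
    out = f
    for k in range(1, 5):
        out = ad.relu(_conv(out, p, f"dec{k}"))
    return _conv(out, p, "dec5")  # no activation on the last layer


def as_tensors(weights: NetWeights, trainable: bool = False) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=trainable) for k, v in weights.params.items()}


# -- numpy-facing API ---------------------------------------------------------


def _to_batch(image, dtype) -> np.ndarray:
    if isinstance(image, GrayImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[None, :, :, None]
    elif arr.ndim == 3:
        arr = arr[None]
    return np.ascontiguousarray(arr, dtype=dtype)


def mc_block(image, cfg: NetConfig, weights: NetWeights) -> np.ndarray:
    """Multi-scale dense feature extraction: (H, W, 1) -> (H, W, C)."""
    x = Tensor(_to_batch(image, cfg.np_dtype))
    return mc_forward(x, as_tensors(weights), cfg).data[0]


def channel_attention(features: np.ndarray, weights: NetWeights) -> np.ndarray:
    cfg = weights.config
    x = Tensor(_to_batch(features, cfg.np_dtype))
    return ca_forward(x, as_tensors(weights), cfg).data[0]


def spatial_attention(features: np.ndarray, weights: NetWeights) -> np.ndarray:
    x = Tensor(_to_batch(features, weights.config.np_dtype))
    return sa_forward(x, as_tensors(weights)).data[0]


def ma_block(features: np.ndarray, weights: NetWeights) -> np.ndarray:
    cfg = weights.config
    x = Tensor(_to_batch(features, cfg.np_dtype))
    return ma_forward(x, as_tensors(weights), cfg).data[0]


def encode(image, weights: NetWeights) -> np.ndarray:
    """Encode one image to an (H, W, C) feature stack.

    The same :class:`NetWeights` object serves both modalities; there is a
    single parameter set by construction (siamese contract).
    """
    cfg = weights.config
    x = Tensor(_to_batch(image, cfg.np_dtype))
    return encode_forward(x, as_tensors(weights), cfg).data[0]


def decode(features: np.ndarray, weights: NetWeights, clip: bool = True) -> np.ndarray:
    """Decode an (H, W, C) stack back to an image.

    Raw decoder output may be negative (the last layer has no activation);
    ``clip`` bounds it to [0, 1] for export.
    """
    cfg = weights.config
    f = Tensor(_to_batch(features, cfg.np_dtype))
    out = decode_forward(f, as_tensors(weights), cfg).data[0, :, :, 0]
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out.astype(np.float64)
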