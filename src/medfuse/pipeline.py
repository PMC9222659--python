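"""End-to-end fusion: encode both sources with shared weights, fuse, decode."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .imgio import GrayImage, ImagePair
from .network import NetWeights, decode, encode, load_weights
from .saliency import FusionParams, ct_weight_map, fuse_baseline, fuse_features

__all__ = ["RunConfig", "fuse_images", "fuse_pair_features"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """A complete inference configuration: weights plus fusion settings."""

    weights_path: Path
    fusion: FusionParams = FusionParams()
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights_path", Path(self.weights_path))
        if not self.weights_path.exists():
            raise ValueError(f"weights file not found: {self.weights_path}")

    def load(self) -> NetWeights:
        return load_weights(self.weights_path)


def fuse_pair_features(
    f_ct: np.ndarray, f_mri: np.ndarray, params: FusionParams
) -> np.ndarray:
    """Apply the configured fusion rule to two encoder feature stacks."""
    if params.strategy == "vsm":
        w1 = ct_weight_map(f_ct, params)
        return fuse_features(
            f_ct, f_mri, w1, gamma=params.gamma, mri_coefficient=params.mri_coefficient
        )
    return fuse_baseline(f_ct, f_mri, params.strategy)


def fuse_images(
    pair: ImagePair,
    weights: NetWeights,
    params: FusionParams = FusionParams(),
) -> GrayImage:
    """Fuse a registered CT/MRI pair into one image.

    Both sources pass through the same encoder weights, the feature stacks
    are combined by the configured strategy, and the decoder reconstructs the
    fused image, clipped to [0, 1] for export.
    """
    f_ct = encode(pair.ct, weights)
    f_mri = encode(pair.mri, weights)
    fused = fuse_pair_features(f_ct, f_mri, params)
    return GrayImage(decode(fused, weights, clip=True))
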