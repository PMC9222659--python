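"""Seeded generator of registered pseudo-CT / pseudo-MRI phantom pairs.

The phantoms emulate the complementarity the fusion method assumes: the CT
member carries a bright dense ring ("skull") over a flat low-intensity
interior, while the MRI member carries a dark ring over a texture-rich soft
tissue interior with optional bright lesions.  Both members share the exact
same geometry masks, so the pairs are pixel-registered by construction.
No CT/MRI physics is simulated.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imgio import GrayImage, ImagePair

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "make_pair",
    "annulus_mask",
    "augment_pair",
    "make_dataset",
]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one phantom pair.

    ``ring_radius_frac`` and ``ring_thickness_frac`` are expressed as
    fractions of the half-size; the dense ring must fit inside the frame and
    the CT bone level must exceed the CT tissue level so the ring is the
    CT-salient structure.
    """

    size: int = 64
    seed: int = 0
    ring_radius_frac: float = 0.78
    ring_thickness_frac: float = 0.14
    ct_bone_level: float = 0.95
    ct_tissue_level: float = 0.25
    mri_texture_scale: float = 6.0
    noise_sd: float = 0.01
    n_lesions: int = 2

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if not 0.0 < self.ring_radius_frac < 1.0:
            raise ValueError("ring_radius_frac must be in (0,1)")
        if not 0.0 < self.ring_thickness_frac < 1.0:
            raise ValueError("ring_thickness_frac must be in (0,1)")
        if self.ring_radius_frac + self.ring_thickness_frac / 2 >= 1.0:
            raise ValueError("ring does not fit inside the image")
        if not self.ct_bone_level > self.ct_tissue_level:
            raise ValueError("ct_bone_level must exceed ct_tissue_level")
        if not 0.0 < self.ct_bone_level <= 1.0 or not 0.0 <= self.ct_tissue_level < 1.0:
            raise ValueError("intensity levels out of range")
        if self.mri_texture_scale <= 0:
            raise ValueError("mri_texture_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


def _radius_grid(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - c, xx - c)


def annulus_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the dense ring; shared by both members of a pair."""
    half = spec.size / 2.0
    r = _radius_grid(spec.size)
    outer = spec.ring_radius_frac * half + spec.ring_thickness_frac * half / 2
    inner = spec.ring_radius_frac * half - spec.ring_thickness_frac * half / 2
    return (r >= inner) & (r <= outer)


def _smooth_texture(size: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited value noise in [0.15, 0.85]; flat if the noise degenerates."""
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=scale)
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.full((size, size), 0.5)
    return 0.15 + 0.7 * (field - lo) / (hi - lo)


def make_pair(spec: PhantomSpec) -> ImagePair:
    """Render one registered pair; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    ring = annulus_mask(spec)
    half = size / 2.0
    inner_r = spec.ring_radius_frac * half - spec.ring_thickness_frac * half / 2
    interior = _radius_grid(size) < inner_r

    ct = np.full((size, size), spec.ct_tissue_level)
    ct[~(ring | interior)] = 0.0  # background outside the head
    ct[ring] = spec.ct_bone_level

    mri = np.zeros((size, size))
    texture = _smooth_texture(size, spec.mri_texture_scale, rng)
    mri[interior] = texture[interior]
    mri[ring] = 0.05  # bone is dark on MRI

    for _ in range(spec.n_lesions):
        cy, cx = rng.uniform(0.3 * size, 0.7 * size, size=2)
        ry, rx = rng.uniform(0.03 * size, 0.08 * size, size=2)
        yy, xx = np.mgrid[0:size, 0:size]
        blob = ((yy - cy) / max(ry, 1.0)) ** 2 + ((xx - cx) / max(rx, 1.0)) ** 2 <= 1.0
        mri[blob & interior] = 0.92

    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, ct.shape)
        mri = mri + rng.normal(0.0, spec.noise_sd, mri.shape)

    return ImagePair(
        ct=GrayImage(np.clip(ct, 0.0, 1.0)),
        mri=GrayImage(np.clip(mri, 0.0, 1.0)),
    )


_ROTATIONS = {0: 0, 90: 1, 180: 2, 270: 3}


def augment_pair(
    pair: ImagePair,
    crop_size: int,
    rotation: int = 0,
    offset: tuple[int, int] = (0, 0),
) -> ImagePair:
    """Apply one identical crop + right-angle rotation to both members.

    Rotations are restricted to multiples of 90 degrees so the transform is
    exact (no interpolation) and registration is trivially preserved.
    """
    if rotation not in _ROTATIONS:
        raise ValueError(f"rotation must be one of {sorted(_ROTATIONS)}, got {rotation}")
    r0, c0 = offset
    h, w = pair.ct.height, pair.ct.width
    if crop_size < 8:
        raise ValueError("crop_size must be >= 8")
    if r0 < 0 or c0 < 0 or r0 + crop_size > h or c0 + crop_size > w:
        raise ValueError(
            f"crop {crop_size}x{crop_size} at offset {offset} exceeds image {h}x{w}"
        )
    k = _ROTATIONS[rotation]

    def xform(img: GrayImage) -> GrayImage:
        window = img.pixels[r0 : r0 + crop_size, c0 : c0 + crop_size]
        return GrayImage(np.rot90(window, k).copy(), source_depth=img.source_depth)

    return ImagePair(ct=xform(pair.ct), mri=xform(pair.mri))


@dataclasses.dataclass(frozen=True)
class PhantomDataset(Sequence):
    """Sequence of phantom pairs with a disjoint train/val/test split."""

    pairs: tuple[ImagePair, ...]
    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    test_idx: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


def make_dataset(
    n_pairs: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    val_frac: float = 0.15,
    test_frac: float = 0.15,
) -> PhantomDataset:
    """Generate ``n_pairs`` jittered, augmented pairs, reproducibly.

    Each pair perturbs the base geometry/texture parameters and applies a
    random right-angle rotation; the split indices partition ``range(n_pairs)``
    disjointly (train gets the remainder, and always at least one pair).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        spec = dataclasses.replace(
            base_spec,
            seed=int(rng.integers(0, 2**31 - 1)),
            ring_radius_frac=float(
                np.clip(base_spec.ring_radius_frac * rng.uniform(0.9, 1.05), 0.3, 0.85)
            ),
            ring_thickness_frac=float(
                np.clip(base_spec.ring_thickness_frac * rng.uniform(0.8, 1.2), 0.04, 0.3)
            ),
            mri_texture_scale=float(base_spec.mri_texture_scale * rng.uniform(0.7, 1.4)),
            n_lesions=int(rng.integers(0, base_spec.n_lesions + 1)),
        )
        pair = make_pair(spec)
        rotation = int(rng.choice([0, 90, 180, 270]))
        pairs.append(augment_pair(pair, crop_size=spec.size, rotation=rotation))

    order = rng.permutation(n_pairs)
    n_val = int(n_pairs * val_frac)
    n_test = int(n_pairs * test_frac)
    val = tuple(int(i) for i in order[:n_val])
    test = tuple(int(i) for i in order[n_val : n_val + n_test])
    train = tuple(int(i) for i in order[n_val + n_test :])
    return PhantomDataset(tuple(pairs), train, val, test)
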