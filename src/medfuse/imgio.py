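"""Reading, writing and normalising co-registered grayscale image pairs.

All internal processing happens on float images in [0, 1]; integer gray
levels appear only where a histogram over discrete levels is required
(see :func:`quantize_levels`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "ImagePair", "load_gray", "save_gray", "quantize_levels"]

#: Rec. 601 luminance weights used when an RGB image is loaded.
_LUMA_601 = np.array([0.299, 0.587, 0.114])

_MIN_SIDE = 8


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """A single-channel intensity raster with values in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1].
    source_depth
        Bit depth of the file the image came from (8 by default); purely
        informational.
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass(frozen=True)
class ImagePair:
    """A co-registered (CT, MRI) pair; registration is assumed, not performed."""

    ct: GrayImage
    mri: GrayImage

    def __post_init__(self) -> None:
        if (self.ct.height, self.ct.width) != (self.mri.height, self.mri.width):
            raise ValueError(
                "CT and MRI must share dimensions; got "
                f"{(self.ct.height, self.ct.width)} vs "
                f"{(self.mri.height, self.mri.width)}"
            )


def load_gray(path: str | Path) -> GrayImage:
    """Load a PNG/TIFF image as a :class:`GrayImage` in [0, 1].

    RGB(A) inputs are collapsed to luminance with Rec. 601 weights; integer
    intensities are rescaled by ``2**depth - 1``.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise OSError(f"could not read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError(f"{path} decodes to a zero-sized image")
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[:, :, :3]
        raw = raw @ _LUMA_601
        # luma of uint inputs is float already; keep the source scale
    if np.issubdtype(np.asarray(raw).dtype, np.floating) and raw.max() <= 1.0:
        return GrayImage(np.clip(raw, 0.0, 1.0), source_depth=8)
    depth = 16 if raw.max() > 255 else 8
    scale = float(2**depth - 1)
    return GrayImage(np.clip(raw / scale, 0.0, 1.0), source_depth=depth)


def save_gray(image: GrayImage, path: str | Path, depth: int = 8) -> None:
    """Write ``image`` as an 8- or 16-bit single-channel PNG/TIFF.

    A save/load round trip reproduces the image to within one quantisation
    step, ``1 / (2**depth - 1)`` per pixel.
    """
    if depth not in (8, 16):
        raise ValueError(f"depth must be 8 or 16, got {depth}")
    scale = 2**depth - 1
    levels = quantize_levels(image, scale + 1)
    data = levels.astype(np.uint8 if depth == 8 else np.uint16)
    iio.imwrite(Path(path), data)


def quantize_levels(image: GrayImage | np.ndarray, levels: int) -> np.ndarray:
    """Map [0, 1] intensities to integer levels ``0 .. levels-1``.

    Value ``v`` maps to ``round(v * (levels - 1))`` with halves rounded away
    from zero, so 0.5 at 256 levels gives 128 (0.5 * 255 = 127.5 -> 128).
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    scaled = px * (levels - 1)
    # np.round rounds halves to even; floor(x + 0.5) rounds away from zero
    # for the non-negative intensities handled here.
    return np.floor(scaled + 0.5).astype(np.int64)
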