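"""Objective fusion-quality metrics: CC, MI, SF, PC, NCIE, SCD.

Each metric scores a fused image ``F`` against the source pair ``(A, B)``
(SF uses the fused image alone).  Conventions, fixed here because the metric
family admits variants:

* MI — sum of the two source-vs-fused mutual informations from 256-bin joint
  histograms, in bits.
* SF — root of mean squared horizontal plus vertical first differences,
  dividing by the number of differences (M*(N-1), (M-1)*N), on the [0, 1]
  intensity scale.
* NCIE — nonlinear correlation information entropy over the K=3 variables
  (A, B, F) with logarithm base b=256.  The pairwise nonlinear correlation
  coefficient uses equal-frequency 256-bin marginals, NCC = 2 - H_b(joint),
  which is exactly 1 for identical inputs and ~0 for independent ones.
* PC — phase-congruency preservation: log-Gabor phase congruency maps and
  their maximum/minimum moment maps are computed for all three images and
  combined as a product of the best source-vs-fused correlations of the
  three maps, unit exponents.
* Pearson correlation of a constant signal is defined as 0, except that two
  identical maps always correlate at 1 (so self-comparisons are exact).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import mutual_info_score

from .imgio import GrayImage, quantize_levels

__all__ = [
    "MetricsReport",
    "metric_cc",
    "metric_mi",
    "metric_sf",
    "metric_pc",
    "metric_ncie",
    "metric_scd",
    "evaluate_dataset",
    "phase_congruency",
]

_NCIE_BASE = 256
_MI_LEVELS = 256


def _arr(image) -> np.ndarray:
    a = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return a


def _check_shapes(*images: np.ndarray) -> None:
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images must share a shape, got {sorted(shapes)}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.array_equal(x, y):
        return 1.0
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return 0.0
    return float((xc * yc).sum() / denom)


def metric_cc(fused, a, b) -> float:
    """Mean Pearson correlation of the fused image with each source."""
    f, a, b = _arr(fused), _arr(a), _arr(b)
    _check_shapes(f, a, b)
    return 0.5 * (_pearson(f, a) + _pearson(f, b))


def _mi_pair(lx: np.ndarray, ly: np.ndarray) -> float:
    joint, _, _ = np.histogram2d(
        lx.ravel(), ly.ravel(), bins=_MI_LEVELS, range=[[0, _MI_LEVELS], [0, _MI_LEVELS]]
    )
    return float(mutual_info_score(None, None, contingency=joint) / np.log(2.0))


def metric_mi(fused, a, b) -> float:
    """MI(F, A) + MI(F, B) in bits, from 256-bin joint histograms."""
    f, a, b = _arr(fused), _arr(a), _arr(b)
    _check_shapes(f, a, b)
    lf = quantize_levels(f, _MI_LEVELS)
    return _mi_pair(lf, quantize_levels(a, _MI_LEVELS)) + _mi_pair(
        lf, quantize_levels(b, _MI_LEVELS)
    )


def metric_sf(fused) -> float:
    """Spatial frequency of the fused image: sqrt(RF^2 + CF^2)."""
    f = _arr(fused)
    if f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError("spatial frequency needs at least a 2x2 image")
    row_diff = np.diff(f, axis=1)  # horizontal first differences
    col_diff = np.diff(f, axis=0)  # vertical first differences
    rf2 = (row_diff**2).sum() / (f.shape[0] * (f.shape[1] - 1))
    cf2 = (col_diff**2).sum() / ((f.shape[0] - 1) * f.shape[1])
    return float(np.sqrt(rf2 + cf2))


def _rank_levels(x: np.ndarray, b: int) -> np.ndarray:
    """Equal-frequency binning of pixel values into b levels (stable ties)."""
    flat = x.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(flat.size, dtype=np.int64)
    ranks[order] = np.arange(flat.size)
    return (ranks * b) // flat.size


def _ncc(lx: np.ndarray, ly: np.ndarray, b: int = _NCIE_BASE) -> float:
    joint, _, _ = np.histogram2d(lx, ly, bins=b, range=[[0, b], [0, b]])
    p = joint[joint > 0] / lx.size
    h_joint = float(-(p * np.log(p)).sum() / np.log(b))
    return 2.0 - h_joint


def metric_ncie(fused, a, b) -> float:
    """Nonlinear correlation information entropy of (A, B, F); at most 1."""
    f, a, b = _arr(fused), _arr(a), _arr(b)
    _check_shapes(f, a, b)
    la, lb, lf = (_rank_levels(x, _NCIE_BASE) for x in (a, b, f))
    r = np.ones((3, 3))
    r[0, 1] = r[1, 0] = _ncc(la, lb)
    r[0, 2] = r[2, 0] = _ncc(la, lf)
    r[1, 2] = r[2, 1] = _ncc(lb, lf)
    lam = np.linalg.eigvalsh(r)
    terms = [
        (l / 3.0) * np.log(l / 3.0) / np.log(_NCIE_BASE) for l in lam if l > 1e-12
    ]
    return float(1.0 + sum(terms))


def metric_scd(fused, a, b) -> float:
    """Sum of correlations of differences: r(F - B, A) + r(F - A, B)."""
    f, a, b = _arr(fused), _arr(a), _arr(b)
    _check_shapes(f, a, b)
    return _pearson(f - b, a) + _pearson(f - a, b)


# -- phase congruency ---------------------------------------------------------


def phase_congruency(
    image,
    nscale: int = 4,
    norient: int = 6,
    min_wavelength: float = 3.0,
    mult: float = 2.1,
    sigma_onf: float = 0.55,
    eps: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-Gabor phase congruency of an image.

    Returns ``(pc, moment_max, moment_min)``: the per-pixel phase congruency
    (maximum over orientations) and the maximum/minimum moments of the
    per-orientation congruency, the classical edge- and corner-strength maps.
    """
    img = _arr(image)
    rows, cols = img.shape
    spectrum = np.fft.fft2(img)

    fy = np.fft.fftfreq(rows)
    fx = np.fft.fftfreq(cols)
    u, v = np.meshgrid(fx, fy)
    radius = np.hypot(u, v)
    radius[0, 0] = 1.0  # avoid log(0) at DC
    theta = np.arctan2(-v, u)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    lowpass = 1.0 / (1.0 + (radius / 0.45) ** (2 * 15))
    log_gabors = []
    for s in range(nscale):
        f0 = 1.0 / (min_wavelength * mult**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_onf) ** 2))
        lg *= lowpass
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = np.pi / norient / 1.5
    pc_theta = []
    angles = []
    for o in range(norient):
        angle = o * np.pi / norient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        sum_e = np.zeros((rows, cols), dtype=complex)
        sum_a = np.zeros((rows, cols))
        for lg in log_gabors:
            response = np.fft.ifft2(spectrum * lg * spread)
            sum_e += response
            sum_a += np.abs(response)
        pc_theta.append(np.abs(sum_e) / (sum_a + eps))
        angles.append(angle)

    pc_stack = np.stack(pc_theta)
    cos_a = np.cos(angles)[:, None, None]
    sin_a = np.sin(angles)[:, None, None]
    a_mom = ((pc_stack * cos_a) ** 2).sum(axis=0)
    c_mom = ((pc_stack * sin_a) ** 2).sum(axis=0)
    b_mom = 2.0 * ((pc_stack * cos_a) * (pc_stack * sin_a)).sum(axis=0)
    root = np.sqrt(b_mom**2 + (a_mom - c_mom) ** 2)
    moment_max = (c_mom + a_mom + root) / 2.0
    moment_min = (c_mom + a_mom - root) / 2.0
    return pc_stack.max(axis=0), moment_max, moment_min


def metric_pc(fused, a, b, **pc_kwargs) -> float:
    """Phase-congruency preservation Q_P in [0, 1].

    For each of the three maps (congruency, maximum moment, minimum moment)
    the factor is the better of the two source-vs-fused Pearson correlations;
    the score is their product with unit exponents, clipped to [0, 1].
    """
    f, a, b = _arr(fused), _arr(a), _arr(b)
    _check_shapes(f, a, b)
    if min(f.shape) < 32:
        raise ValueError("phase congruency needs images of at least 32 pixels a side")
    maps_f = phase_congruency(f, **pc_kwargs)
    maps_a = phase_congruency(a, **pc_kwargs)
    maps_b = phase_congruency(b, **pc_kwargs)
    score = 1.0
    for mf, ma, mb in zip(maps_f, maps_a, maps_b):
        score *= max(_pearson(ma, mf), _pearson(mb, mf))
    return float(np.clip(score, 0.0, 1.0))


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Dataset-mean fusion scores plus the per-triple values."""

    cc: float
    mi: float
    sf: float
    pc: float
    ncie: float
    scd: float
    n_images: int
    per_image: tuple[dict, ...] = ()


def evaluate_dataset(triples: Sequence[tuple]) -> MetricsReport:
    """Average the six metrics over (fused, ct, mri) triples."""
    if len(triples) == 0:
        raise ValueError("need at least one (fused, ct, mri) triple")
    rows = []
    for f, a, b in triples:
        rows.append(
            {
                "cc": metric_cc(f, a, b),
                "mi": metric_mi(f, a, b),
                "sf": metric_sf(f),
                "pc": metric_pc(f, a, b),
                "ncie": metric_ncie(f, a, b),
                "scd": metric_scd(f, a, b),
            }
        )
    means = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
    return MetricsReport(n_images=len(rows), per_image=tuple(rows), **means)


def entropy_bits(image, levels: int = _MI_LEVELS) -> float:
    """Shannon entropy of the quantised intensity histogram, in bits."""
    lv = quantize_levels(_arr(image), levels)
    counts = np.bincount(lv.ravel(), minlength=levels)
    return float(stats.entropy(counts, base=2))
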