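"""Texture features: Haralick co-occurrence statistics and Gabor energies.

The gray-level co-occurrence matrix (GLCM) is computed on masked pixels only
(both pixels of a pair must lie inside the mask), with intensities quantized
to 8 levels over the masked intensity range (ties assigned to the lower bin),
symmetrized and normalized. Thirteen classical Haralick statistics are taken
at 4 angles x 8 distances = 416 values, plus Gabor filter energy at
4 orientations x 9 wavelengths = 36 values, for 452 in total.

Degenerate cases follow documented sentinel rules: if a mask admits no pixel
pair at some offset, or a statistic is undefined (e.g. correlation of a
constant patch), the value is 0 and the event is logged.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import gabor

from .registry import (
    GABOR_THETAS,
    GABOR_WAVELENGTHS,
    GLCM_ANGLES,
    GLCM_DISTANCES,
    HARALICK_NAMES,
)

logger = logging.getLogger(__name__)

N_LEVELS = 8

# (row, col) unit offsets for each angle, in image coordinates.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

# Cap the Gaussian envelope of long-wavelength Gabor kernels so the filter
# stays local to a 64 px crop.
_GABOR_SIGMA_CAP = 8.0


def quantize(image: np.ndarray, mask: np.ndarray, levels: int = N_LEVELS) -> np.ndarray:
    """Quantize masked intensities to ``levels`` bins; -1 outside the mask."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    q = np.full(image.shape, -1, dtype=np.int64)
    if not mask.any():
        return q
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        q[mask] = 0
        return q
    binned = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    q[mask] = np.clip(binned[mask], 0, levels - 1)
    return q


def cooccurrence(
    quantized: np.ndarray, offset: tuple[int, int], levels: int = N_LEVELS
) -> np.ndarray:
    """Symmetric, normalized GLCM for one (row, col) offset.

    Returns the ``levels x levels`` probability matrix; all-zero if the mask
    admits no valid pixel pair at this offset.
    """
    dr, dc = offset
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((levels, levels))
    a = quantized[r0:r1, c0:c1]
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        return np.zeros((levels, levels))
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    counts = counts + counts.T  # symmetrize
    return counts / counts.sum()


def haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized symmetric GLCM.

    Entropies use log base 2. An all-zero matrix (no valid pairs) yields the
    sentinel vector of zeros; statistics with zero denominators
    (correlation, IMC1) are set to 0.
    """
    L = P.shape[0]
    total = P.sum()
    if total <= 0:
        return np.zeros(len(HARALICK_NAMES))
    P = P / total
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # p_{x+y}(k), k = 0..2L-2 and p_{|x-y|}(k), k = 0..L-1
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    def entropy(p):
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())

    asm = float((P ** 2).sum())
    contrast = float((k_diff ** 2 * p_diff).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = entropy(p_sum)
    ent = entropy(P.ravel())
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = entropy(p_diff)

    # information measures of correlation
    pxy = np.outer(px, py)
    nz = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    hx, hy = entropy(px), entropy(py)
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            ent,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def gabor_energies(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean squared Gabor response over the mask, 4 orientations x 9
    wavelengths (DC removed by subtracting the masked mean first)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    work = np.where(mask, image - image[mask].mean(), 0.0)
    out = np.empty(len(GABOR_THETAS) * len(GABOR_WAVELENGTHS))
    k = 0
    for theta in GABOR_THETAS:
        rad = np.deg2rad(theta)
        for wl in GABOR_WAVELENGTHS:
            sigma = min(0.56 * wl, _GABOR_SIGMA_CAP)
            real, imag = gabor(
                work, frequency=1.0 / wl, theta=rad, sigma_x=sigma, sigma_y=sigma
            )
            out[k] = float((real[mask] ** 2 + imag[mask] ** 2).mean())
            k += 1
    return out


def texture_features(
    image: np.ndarray, mask: np.ndarray, levels: int = N_LEVELS
) -> np.ndarray:
    """All 452 texture features in registry order."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    q = quantize(image, mask, levels)
    values = []
    for d in GLCM_DISTANCES:
        for angle in GLCM_ANGLES:
            dr, dc = _ANGLE_OFFSETS[angle]
            P = cooccurrence(q, (dr * d, dc * d), levels)
            if P.sum() == 0:
                logger.warning(
                    "no pixel pairs at distance %d angle %d; sentinel 0", d, angle
                )
            values.append(haralick_from_glcm(P))
    glcm_part = np.concatenate(values)
    return np.concatenate([glcm_part, gabor_energies(image, mask)])
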