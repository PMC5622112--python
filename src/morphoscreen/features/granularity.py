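"""Granular spectrum: per-scale fractions of masked intensity removed by a
granulometry of increasing structuring-element size.

At each scale s = 1..10 the image is eroded with a disk of radius s and then
regrown by morphological reconstruction under the original; the feature is
the fraction of total masked intensity lost between scales s-1 and s. The
reconstruction step makes the sieve exact: structures too small (or too
disconnected) to survive the erosion are removed, while larger structures
are restored intact. Because erosions with nested disks are pointwise
non-increasing and reconstruction is monotone, every bin is non-negative
and the cumulative sum is bounded by 1; a constant-intensity cell yields an
all-zero spectrum.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import disk, erosion, reconstruction

from .registry import GRANULARITY_SCALES


def granularity_features(
    image: np.ndarray, mask: np.ndarray, scales=GRANULARITY_SCALES
) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    work = np.where(mask, image, 0.0)
    total = work[mask].sum()
    if total <= 0:
        raise ValueError("zero total intensity inside the mask")

    prev_sum = total  # scale 0: the image itself
    spectrum = np.empty(len(scales))
    for k, s in enumerate(scales):
        eroded = erosion(work, disk(s))
        restored = reconstruction(np.minimum(eroded, work), work, method="dilation")
        cur_sum = restored[mask].sum()
        spectrum[k] = max(prev_sum - cur_sum, 0.0) / total
        prev_sum = min(prev_sum, cur_sum)
    return spectrum
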