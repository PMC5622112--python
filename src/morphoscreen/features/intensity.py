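"""Intensity features: masked intensity statistics, boundary-ring statistics,
mass displacement, centroid, and a 10-ring equal-area radial profile."""

from __future__ import annotations

import numpy as np
from skimage.morphology import disk, erosion


def _stats10(v: np.ndarray) -> list[float]:
    """integrated, mean, median, std, MAD, min, max, q25, q75, IQR."""
    med = float(np.median(v))
    q25, q75 = np.percentile(v, [25, 75])
    return [
        float(v.sum()),
        float(v.mean()),
        med,
        float(v.std()),
        float(np.median(np.abs(v - med))),
        float(v.min()),
        float(v.max()),
        float(q25),
        float(q75),
        float(q75 - q25),
    ]


def intensity_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """All 43 intensity features in registry order."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    values = _stats10(image[mask])

    ring = mask & ~erosion(mask, disk(1))
    if not ring.any():
        ring = mask
    values += _stats10(image[ring])

    # mass displacement: binary centroid vs intensity-weighted centroid
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    w = image[mask]
    wsum = w.sum()
    if wsum > 0:
        wy, wx = (ys * w).sum() / wsum, (xs * w).sum() / wsum
        displacement = float(np.hypot(wy - cy, wx - cx))
    else:
        displacement = 0.0
    values += [displacement, float(cx), float(cy)]

    # equal-area radial profile: masked pixels ranked by distance from the
    # binary centroid, split into 10 equal-count rings (mean and CV each)
    r = np.hypot(ys - cy, xs - cx)
    order = np.argsort(r, kind="stable")
    groups = np.array_split(image[mask][order], 10)
    means, cvs = [], []
    for g in groups:
        if g.size == 0:
            means.append(0.0)
            cvs.append(0.0)
            continue
        m = float(g.mean())
        means.append(m)
        cvs.append(float(g.std() / m) if m != 0 else 0.0)
    values += means + cvs

    return np.asarray(values)
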