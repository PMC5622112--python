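"""Geometry features: 13 shape scalars and 30 Zernike moment magnitudes.

Zernike moments are computed on the binary mask mapped to the unit disk
(centroid-centered, radius = the mask's minimum enclosing radius about the
centroid), the usual convention for shape — not intensity — descriptors.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops

from .registry import ZERNIKE_ORDERS


def _feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """(max, min) Feret diameter of the mask via the convex hull.

    Max: largest pairwise distance between hull vertices. Min: smallest
    width over all hull-edge support directions (rotating calipers).
    Degenerate masks (< 3 non-collinear pixels) fall back to the pixel
    bounding extent.
    """
    pts = np.argwhere(mask).astype(float)
    try:
        hull = ConvexHull(pts)
        vertices = pts[hull.vertices]
    except (QhullError, IndexError):
        span = pts.max(axis=0) - pts.min(axis=0)
        ext = float(np.hypot(*span)) + 1.0
        return ext, float(min(span) + 1.0)

    diffs = vertices[:, None, :] - vertices[None, :, :]
    feret_max = float(np.sqrt((diffs ** 2).sum(-1)).max())

    edges = np.roll(vertices, -1, axis=0) - vertices
    lengths = np.linalg.norm(edges, axis=1)
    edges = edges[lengths > 0] / lengths[lengths > 0, None]
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1)
    proj = vertices @ normals.T  # (n_vertices, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min()) if widths.size else feret_max
    # +1 px accounts for the unit extent of boundary pixels
    return feret_max + 1.0, feret_min + 1.0


def shape_features(mask: np.ndarray) -> np.ndarray:
    """The 13 shape scalars in registry order."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    # Crofton estimator: far less biased than pixel-edge counting on
    # smooth boundaries (a digitized disk's form factor stays near 1)
    perimeter = float(props.perimeter_crofton)
    form_factor = 4.0 * math.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    compactness = perimeter ** 2 / (4.0 * math.pi * area) if area > 0 else 0.0
    feret_max, feret_min = _feret_diameters(mask)
    return np.array(
        [
            area,
            perimeter,
            form_factor,
            float(props.solidity),
            float(props.extent),
            float(props.eccentricity),
            float(props.axis_major_length),
            float(props.axis_minor_length),
            float(props.orientation),
            compactness,
            float(props.equivalent_diameter_area),
            feret_max,
            feret_min,
        ]
    )


def _radial_polynomial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += c * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(mask: np.ndarray) -> np.ndarray:
    """|Z_nm| for n = 0..9 and all same-parity m >= 0 (30 values).

    The mask is treated as a uniform unit-mass density on the unit disk, so
    the magnitudes are invariant to translation and scale and, for m > 0,
    vanish on rotationally symmetric shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    r = np.hypot(dy, dx)
    radius = r.max()
    if radius == 0:  # single pixel
        rho = r
    else:
        rho = r / radius
    theta = np.arctan2(dy, dx)
    npix = mask.sum()

    out = np.empty(len(ZERNIKE_ORDERS))
    for k, (n, m) in enumerate(ZERNIKE_ORDERS):
        R = _radial_polynomial(n, m, rho)
        z = (n + 1) / math.pi * np.mean(R * np.exp(-1j * m * theta))
        out[k] = abs(z)
    return out


def geometry_features(mask: np.ndarray) -> np.ndarray:
    """All 43 geometry features (13 shape + 30 Zernike), registry order."""
    return np.concatenate([shape_features(mask), zernike_magnitudes(mask)])
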