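"""Frame reconstruction from 1D line-scan waveforms and single-cell segmentation.

A line-scan instrument emits one intensity profile per laser pulse; 2D frames
are recovered by stacking consecutive profiles. Cells are then segmented with
a deliberately minimal standard chain: per-frame min-max normalization, Otsu
thresholding, morphological closing, hole filling, largest connected
component, and a minimum-area filter, followed by a fixed-size crop centered
on the mask centroid.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .types import CellImage

logger = logging.getLogger(__name__)

DEFAULT_MIN_AREA = 50
DEFAULT_CROP_SIZE = 64
DEFAULT_CLOSING_RADIUS = 2


class NoCellFoundError(ValueError):
    """Raised when a frame contains no component surviving the area filter."""


def stack_linescans(
    waveform: np.ndarray, samples_per_line: int, lines_per_frame: int
) -> list[np.ndarray]:
    """Reshape a 1D waveform into consecutive 2D frames.

    The waveform length must be divisible by ``samples_per_line``; trailing
    lines that do not fill a complete frame are discarded with a warning.
    """
    waveform = np.asarray(waveform)
    if waveform.ndim != 1:
        raise ValueError("waveform must be 1D")
    if samples_per_line <= 0 or lines_per_frame <= 0:
        raise ValueError("samples_per_line and lines_per_frame must be positive")
    if waveform.size % samples_per_line != 0:
        raise ValueError(
            f"waveform length {waveform.size} is not divisible by "
            f"samples_per_line {samples_per_line}"
        )
    n_lines = waveform.size // samples_per_line
    n_frames = n_lines // lines_per_frame
    leftover = n_lines - n_frames * lines_per_frame
    if leftover:
        logger.warning("discarding trailing partial frame (%d lines)", leftover)
    usable = waveform[: n_frames * lines_per_frame * samples_per_line]
    stacked = usable.reshape(n_frames, lines_per_frame, samples_per_line)
    return [stacked[i] for i in range(n_frames)]


def detect_cell_frames(
    frames: list[np.ndarray], min_contrast: float = 0.1
) -> list[int]:
    """Indices of frames whose median-filtered intensity range reaches
    ``min_contrast``; background-only frames fall below it."""
    if len(frames) == 0:
        raise ValueError("frames must be nonempty")
    hits = []
    for i, frame in enumerate(frames):
        smoothed = ndimage.median_filter(np.asarray(frame, dtype=float), size=3)
        if np.ptp(smoothed) >= min_contrast:
            hits.append(i)
    return hits


def _refine_threshold(norm: np.ndarray, t: float, iters: int = 50) -> float:
    """Isodata-style refinement: move the cut to the midpoint of the two
    class means (Otsu's criterion under-cuts soft object boundaries)."""
    for _ in range(iters):
        above = norm > t
        if not above.any() or above.all():
            break
        t_new = 0.5 * (norm[above].mean() + norm[~above].mean())
        if abs(t_new - t) < 1e-6:
            break
        t = t_new
    return t


def segment_cell(
    frame: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    crop_size: int = DEFAULT_CROP_SIZE,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    min_contrast: float = 0.05,
    frame_id: str | int | None = None,
) -> CellImage:
    """Segment the single largest cell in a frame and crop a fixed window.

    The frame is min-max normalized to [0, 1] and thresholded (Otsu start,
    isodata refinement; the minority side of the cut is the cell, since a
    frame is mostly background). Morphological closing and hole filling
    define connectivity, the largest connected component is kept, and the
    final mask is the thresholded pixels — with enclosed holes filled —
    inside that component, so the closing cannot thicken a clean boundary.
    Components below ``min_area`` are rejected. The crop is ``crop_size``
    square, centered on the mask centroid and padded with the median
    background intensity where it extends past the frame.

    Raises
    ------
    NoCellFoundError
        If the frame lacks contrast or no component survives the area filter.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(ndimage.median_filter(frame, size=3)) < min_contrast:
        raise NoCellFoundError(f"frame {frame_id!r}: no contrast, no cell")
    lo, hi = frame.min(), frame.max()
    norm = (frame - lo) / (hi - lo)

    t = _refine_threshold(norm, threshold_otsu(norm))
    above = norm > t
    fg = above if above.mean() <= 0.5 else ~above
    support = ndimage.binary_fill_holes(closing(fg, disk(closing_radius)))

    labeled, n = ndimage.label(support)
    if n == 0:
        raise NoCellFoundError(f"frame {frame_id!r}: nothing above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    component = labeled == best
    mask = component & ndimage.binary_fill_holes(fg)
    labeled2, n2 = ndimage.label(mask)
    if n2 > 1:  # noise can split the component at thin necks
        sizes2 = ndimage.sum_labels(np.ones_like(labeled2), labeled2, range(1, n2 + 1))
        mask = labeled2 == int(np.argmax(sizes2)) + 1
    if mask.sum() < min_area:
        raise NoCellFoundError(
            f"frame {frame_id!r}: largest component {int(mask.sum())} px "
            f"below min_area {min_area}"
        )

    cy, cx = ndimage.center_of_mass(mask)
    half = crop_size // 2
    r0 = int(round(cy)) - half
    c0 = int(round(cx)) - half
    background = float(np.median(norm[~mask]))

    crop = np.full((crop_size, crop_size), background)
    crop_mask = np.zeros((crop_size, crop_size), dtype=bool)
    h, w = norm.shape
    rs, re = max(r0, 0), min(r0 + crop_size, h)
    cs, ce = max(c0, 0), min(c0 + crop_size, w)
    crop[rs - r0 : re - r0, cs - c0 : ce - c0] = norm[rs:re, cs:ce]
    crop_mask[rs - r0 : re - r0, cs - c0 : ce - c0] = mask[rs:re, cs:ce]

    return CellImage(
        pixels=crop,
        mask=crop_mask,
        provenance={
            "frame_id": frame_id,
            "crop_offset": (r0, c0),
            "mask_area": int(mask.sum()),
            "otsu_threshold": float(t),
        },
    )


def segment_frames(
    frames: list[np.ndarray],
    min_contrast: float = 0.1,
    **kwargs,
) -> list[CellImage]:
    """Detect and segment every cell-bearing frame; failures are logged and
    skipped."""
    cells = []
    for i in detect_cell_frames(frames, min_contrast=min_contrast):
        try:
            cells.append(segment_cell(frames[i], frame_id=i, **kwargs))
        except NoCellFoundError as exc:
            logger.warning("skipping frame %d: %s", i, exc)
    return cells
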