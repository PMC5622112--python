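"""Shared in-memory containers for the imaging pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CellImage:
    """A single segmented (or synthesized) cell.

    Attributes
    ----------
    pixels : 2D float array of normalized intensities in [0, 1], row-major.
    mask : 2D boolean array, same shape as ``pixels``; True marks cell pixels.
    provenance : free-form metadata (source frame id, crop offsets, seed, ...).
    """

    pixels: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FeatureVector:
    """The 548-dimensional morphological profile of one cell."""

    values: np.ndarray
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature vector must be 1D")
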