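"""Assemble the full 548-feature profile of a cell."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..synthetic import FEATURE_COLUMNS, META_COLUMNS
from ..types import CellImage, FeatureVector
from .geometry import geometry_features
from .granularity import granularity_features
from .intensity import intensity_features
from .registry import N_FEATURES
from .texture import texture_features

logger = logging.getLogger(__name__)


def extract_features(cell: CellImage) -> FeatureVector:
    """Concatenate geometry | granularity | intensity | texture (548 values).

    Non-finite values (possible on degenerate patches) are replaced by the
    sentinel 0 and logged with the cell id; the output is always finite.
    """
    cell_id = cell.provenance.get("cell_id") or cell.provenance.get("frame_id")
    try:
        vec = np.concatenate(
            [
                geometry_features(cell.mask),
                granularity_features(cell.pixels, cell.mask),
                intensity_features(cell.pixels, cell.mask),
                texture_features(cell.pixels, cell.mask),
            ]
        )
    except ValueError as exc:
        raise ValueError(f"feature extraction failed for cell {cell_id!r}: {exc}")
    assert vec.shape == (N_FEATURES,)
    bad = ~np.isfinite(vec)
    if bad.any():
        logger.warning(
            "cell %r: %d non-finite feature value(s) replaced by 0",
            cell_id,
            int(bad.sum()),
        )
        vec = np.where(bad, 0.0, vec)
    return FeatureVector(values=vec, cell_id=str(cell_id) if cell_id else None)


def extract_table(
    cells: list[CellImage],
    experiment: int = 1,
    duration_h: int = 24,
    dose_M: float = 0.0,
    label: str | None = None,
) -> pd.DataFrame:
    """Extract features from many cells into a standard feature table."""
    if label is None:
        label = "treated" if dose_M > 0 else "control"
    rows = []
    ids = []
    for i, cell in enumerate(cells):
        fv = extract_features(cell)
        rows.append(fv.values)
        ids.append(fv.cell_id or f"cell-{i:05d}")
    df = pd.DataFrame(np.asarray(rows), columns=FEATURE_COLUMNS)
    df.insert(0, "label", label)
    df.insert(0, "dose_M", dose_M)
    df.insert(0, "duration_h", duration_h)
    df.insert(0, "experiment", experiment)
    df.insert(0, "cell_id", ids)
    return df[META_COLUMNS + FEATURE_COLUMNS]
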