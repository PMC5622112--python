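"""File formats: 16-bit cell TIFFs with JSON sidecars, feature-table CSV,
waveforms, and model JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import LinearSVMModel
from .synthetic import FEATURE_COLUMNS, META_COLUMNS
from .types import CellImage

_U16 = 65535


def save_cell(cell: CellImage, path: str | Path) -> None:
    """Write a cell as 16-bit grayscale TIFF + mask TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.round(cell.pixels * _U16).astype(np.uint16))
    tifffile.imwrite(
        path.with_suffix(".mask.tif"), cell.mask.astype(np.uint16) * _U16
    )
    sidecar = {"provenance": _jsonable(cell.provenance)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_cell(path: str | Path) -> CellImage:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float) / _U16
    mask = tifffile.imread(path.with_suffix(".mask.tif")) > 0
    provenance = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", {})
    return CellImage(pixels=pixels, mask=mask, provenance=provenance)


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table[META_COLUMNS + FEATURE_COLUMNS].to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS + FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"not a feature table: missing columns {missing[:3]}"
            + ("..." if len(missing) > 3 else "")
        )
    return table


def save_waveform(waveform: np.ndarray, path: str | Path) -> None:
    """Delimited-text waveform, one sample per line."""
    np.savetxt(path, np.asarray(waveform), fmt="%.8f")


def load_waveform(path: str | Path) -> np.ndarray:
    return np.loadtxt(path)


def save_model(model: LinearSVMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path) -> LinearSVMModel:
    return LinearSVMModel.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
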