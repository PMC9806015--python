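"""Plain-text and image I/O for cell tables, scenes and feature vectors.

Cell tables travel as CSV with semicolon-joined marker and level fields
(columns: cell_id, x, y, panel, markers, levels, region); scenes are RGB
TIFF/PNG plus a 16-bit label TIFF; feature rows are wide CSVs with missing
values encoded as empty fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

CELL_COLUMNS = ["cell_id", "x", "y", "panel", "markers", "levels", "region"]


def cells_to_csv(cells: pd.DataFrame, path) -> None:
    """Write a cell table, serialising marker sets and level maps."""
    out = cells.copy()
    out["markers"] = [";".join(sorted(m)) for m in out["markers"]]
    out["levels"] = [
        ";".join(f"{k}={v}" for k, v in sorted(lv.items())) for lv in out["levels"]
    ]
    if "region" not in out.columns:
        out["region"] = "none"
    out[CELL_COLUMNS].to_csv(path, index=False)


def cells_from_csv(path) -> pd.DataFrame:
    """Read a cell table written by :func:`cells_to_csv`."""
    raw = pd.read_csv(path, keep_default_na=False)
    raw["markers"] = [
        frozenset(m.split(";")) if m else frozenset() for m in raw["markers"]
    ]
    raw["levels"] = [
        dict(kv.split("=") for kv in s.split(";")) if s else {}
        for s in raw["levels"]
    ]
    return raw


def write_scene(scene, rgb_path, label_path) -> None:
    """Write the composite RGB and the 16-bit ground-truth label mask."""
    tifffile.imwrite(rgb_path, scene.rgb)
    tifffile.imwrite(label_path, scene.ground_truth.label_mask.astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def features_to_csv(rows: pd.DataFrame, path) -> None:
    """Wide per-slide or per-patient feature CSV; NaN becomes empty."""
    rows.to_csv(path, index=True, na_rep="")
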