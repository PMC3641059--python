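"""TIFF and manifest I/O.

Fields are stored as one 16-bit grayscale TIFF per channel per field, tied
together by a plate-layout manifest CSV (strain, condition, field_index,
red_path, green_path) and, for synthetic screens, a truth-table CSV.
"""

from __future__ import annotations

import os
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

from .imgproc import Field2C
from .simgen import ScreenSimConfig, simulate_screen

__all__ = [
    "MANIFEST_COLUMNS",
    "read_tiff",
    "write_tiff",
    "read_manifest",
    "iter_manifest_fields",
    "write_screen",
]

MANIFEST_COLUMNS = ["strain", "condition", "field_index", "red_path", "green_path"]


def read_tiff(path: str) -> np.ndarray:
    """Read a grayscale TIFF image or stack as float64."""
    return tifffile.imread(path).astype(float)


def write_tiff(path: str, image: np.ndarray) -> None:
    """Write an intensity image (or stack) as 16-bit unsigned TIFF."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def iter_manifest_fields(manifest: pd.DataFrame) -> Iterator[Field2C]:
    """Load each manifest row as a Field2C (rows with bad paths are skipped
    with a warning that names the row number)."""
    import logging

    logger = logging.getLogger(__name__)
    for idx, row in manifest.iterrows():
        try:
            yield Field2C(
                red=read_tiff(row["red_path"]),
                green=read_tiff(row["green_path"]),
                strain=str(row["strain"]),
                condition=str(row["condition"]),
                field_index=int(row["field_index"]),
            )
        except (OSError, ValueError) as exc:
            logger.warning("manifest row %s unreadable, skipped: %s", idx, exc)


def write_screen(config: ScreenSimConfig, out_dir: str) -> tuple[str, str]:
    """Render a synthetic screen to disk.

    Writes per-field TIFFs plus ``manifest.csv`` and ``truth.csv`` under
    ``out_dir``; returns their paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for strain, condition, fi, fld, truth in simulate_screen(config):
        red_path = os.path.join(out_dir, f"{strain}_{condition}_f{fi}_red.tif")
        green_path = os.path.join(out_dir, f"{strain}_{condition}_f{fi}_green.tif")
        write_tiff(red_path, fld.red)
        write_tiff(green_path, fld.green)
        manifest_rows.append((strain, condition, fi, red_path, green_path))
        truth_rows.append(
            (strain, condition, fi, truth.is_interactor, len(truth.anchor_coordinates))
        )
    manifest_path = os.path.join(out_dir, "manifest.csv")
    truth_path = os.path.join(out_dir, "truth.csv")
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    pd.DataFrame(
        truth_rows,
        columns=["strain", "condition", "field_index", "is_interactor", "n_anchors"],
    ).to_csv(truth_path, index=False)
    return manifest_path, truth_path
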