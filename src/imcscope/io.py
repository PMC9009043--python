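"""Readers and writers for every on-disk artifact.

Conventions, stated once and used everywhere:

* coordinates are 0-based ``(row, col)`` at pixel centers;
* label masks use 0 for background and ``k > 0`` for cell ``k``;
* the interchange image format is (OME-)TIFF, channel-first; proprietary
  acquisition formats (.mcd/.txt) are out of scope;
* all writers are deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .panel import MarkerPanel

CELL_TABLE_INDEX_COLS = ["roi_id", "cell_id", "centroid_row", "centroid_col", "area_px"]


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its contract."""


@dataclass
class RoiImage:
    """One ROI's channel x row x col intensity stack plus metadata.

    ``stack`` holds nonnegative, finite intensities with one plane per
    panel channel; ``pixel_size_um`` defaults to the ~1 um ablation spot
    of an IMC acquisition.
    """

    roi_id: str
    stack: np.ndarray
    panel: MarkerPanel
    cohort: str = "unknown"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise FormatError("stack must be channels x rows x cols")
        if self.stack.shape[0] != len(self.panel):
            raise FormatError(
                f"channel mismatch: panel has {len(self.panel)} channels, "
                f"stack has {self.stack.shape[0]}"
            )
        if not np.all(np.isfinite(self.stack)) or np.any(self.stack < 0):
            raise FormatError("stack intensities must be finite and >= 0")
        if self.cohort not in ("NR", "CR", "unknown"):
            raise FormatError(f"cohort must be NR, CR or unknown, got {self.cohort!r}")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.stack.shape[1], self.stack.shape[2]

    def channel(self, marker: str) -> np.ndarray:
        return self.stack[self.panel.index_of(marker)]


def write_roi(roi: RoiImage, path: str | Path) -> None:
    """Write an ROI as a channel-first multi-page TIFF with JSON metadata."""
    meta = {
        "roi_id": roi.roi_id,
        "cohort": roi.cohort,
        "pixel_size_um": roi.pixel_size_um,
        "markers": list(roi.panel.markers),
    }
    tifffile.imwrite(
        str(path),
        roi.stack,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
    )


def read_roi(path: str | Path, panel: MarkerPanel) -> RoiImage:
    """Read a single- or multi-page TIFF into an :class:`RoiImage`.

    The channel count must match the panel; metadata written by
    :func:`write_roi` is recovered, otherwise cohort is ``unknown`` and the
    roi_id falls back to the file stem.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected 2D or 3D TIFF, got shape {stack.shape}")
    if stack.shape[0] != len(panel):
        raise FormatError(
            f"{path}: channel mismatch, expected {len(panel)} channels "
            f"({', '.join(panel.markers)}), found {stack.shape[0]}"
        )
    roi_id, cohort, pixel_size = path.stem, "unknown", 1.0
    if desc:
        try:
            meta = json.loads(desc)
            roi_id = meta.get("roi_id", roi_id)
            cohort = meta.get("cohort", cohort)
            pixel_size = float(meta.get("pixel_size_um", pixel_size))
        except (json.JSONDecodeError, TypeError):
            pass
    return RoiImage(
        roi_id=roi_id, stack=stack, panel=panel, cohort=cohort, pixel_size_um=pixel_size
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit TIFF, promoting to 32-bit when needed."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if np.any(mask < 0):
        raise ValueError("mask labels must be nonnegative")
    dtype = np.uint16 if mask.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(str(path), mask.astype(dtype), photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(str(path))
    if mask.ndim != 2:
        raise FormatError(f"{path}: label mask must be a single 2D page")
    return mask.astype(np.int64)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell table (one row per cell, marker columns after the
    positional columns) with full float precision.

    ``%.17g`` round-trips IEEE doubles exactly, comfortably beyond the
    9-significant-digit contract.
    """
    _check_cell_table(cells)
    cols = CELL_TABLE_INDEX_COLS + [
        c for c in cells.columns if c not in CELL_TABLE_INDEX_COLS
    ]
    cells[cols].to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path: str | Path, panel: MarkerPanel | None = None) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_INDEX_COLS if c not in cells.columns]
    if missing:
        raise FormatError(f"cell table missing columns: {missing}")
    if panel is not None:
        absent = [m for m in panel.markers if m not in cells.columns]
        if absent:
            raise FormatError(f"cell table missing marker columns: {absent}")
    _check_cell_table(cells)
    return cells


def _check_cell_table(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_TABLE_INDEX_COLS if c not in cells.columns]
    if missing:
        raise FormatError(f"cell table missing columns: {missing}")
    if cells.duplicated(subset=["roi_id", "cell_id"]).any():
        dupes = cells.loc[
            cells.duplicated(subset=["roi_id", "cell_id"]), ["roi_id", "cell_id"]
        ]
        raise FormatError(
            f"duplicate (roi_id, cell_id) pairs: {dupes.values[:5].tolist()}"
        )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
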