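"""Spatial reconstruction: per-well values back onto the section grid.

The inverse of the extraction step: quantified (and normalized) per-well
signals are routed through the analysis-plate layout back to their section
cells, rendered as a nearest-neighbor block raster (one block per well —
the plate's true resolution), and optionally alpha-blended over a photo of
the section taken before lysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image

from .geometry import AnalysisLayout, SectionMatrix
from .quantify import NormalizedValue

__all__ = [
    "ValueGrid",
    "RenderConfig",
    "SectionPhoto",
    "grid_from_records",
    "render",
    "overlay",
    "export_grid",
    "load_grid_tsv",
    "save_png",
    "jaccard",
]


@dataclass
class ValueGrid:
    """Values over the section-matrix window; NaN marks invalid cells."""

    values: np.ndarray
    valid: np.ndarray
    assay_id: str = ""
    normalization: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share a shape")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("valid values must be non-negative")
        self.values = self.values.copy()
        self.values[~self.valid] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def max_valid(self) -> float:
        if not self.valid.any():
            raise ValueError("grid has no valid cells")
        return float(np.nanmax(self.values))


@dataclass(frozen=True)
class RenderConfig:
    colormap: str = "viridis"
    scaling: str = "linear"          # "linear" | "log"
    upsample: int = 8
    invalid_policy: str = "transparent"  # "transparent" | "zero"
    alpha: float = 0.7               # overlay blend weight

    def __post_init__(self) -> None:
        if self.upsample < 1:
            raise ValueError("upsample must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.scaling not in ("linear", "log"):
            raise ValueError("scaling must be 'linear' or 'log'")
        if self.invalid_policy not in ("transparent", "zero"):
            raise ValueError("invalid policy must be 'transparent' or 'zero'")


@dataclass
class SectionPhoto:
    """A photo of the section with a scale+translation registration.

    ``px = px_per_mm * mm + offset_px`` maps plate mm coordinates to photo
    pixels, axis-wise.
    """

    image: np.ndarray  # (H, W, 3|4) uint8
    px_per_mm: float
    offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] not in (3, 4):
            raise ValueError("photo must be an RGB(A) raster")
        if self.px_per_mm == 0:
            raise ValueError("registration transform must be invertible (nonzero scale)")


def grid_from_records(
    values: Mapping[str, float | NormalizedValue | None],
    matrix: SectionMatrix,
    layout: AnalysisLayout,
    assay_id: str = "",
    normalization: str = "",
) -> ValueGrid:
    """Place per-analysis-well values at their section cells.

    ``values`` is keyed by analysis well label; entries may be floats,
    :class:`NormalizedValue` (its ratio is used when valid) or None.
    Reference and blank wells are ignored — they never reach the grid.
    Missing, None and invalid entries yield invalid cells.
    """
    grid = np.full(matrix.shape, np.nan)
    valid = np.zeros(matrix.shape, dtype=bool)
    for well, v in values.items():
        sample = layout.sample_for_well(well)
        if sample is None:  # reference / blank well: not a section sample
            continue
        if isinstance(v, NormalizedValue):
            v = v.ratio if v.valid else None
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        cell = matrix.cell_of_sample(sample)
        grid[cell] = float(v)
        valid[cell] = True
    return ValueGrid(grid, valid, assay_id=assay_id, normalization=normalization)


def render(grid: ValueGrid, config: RenderConfig = RenderConfig()) -> np.ndarray:
    """Render a grid to an RGBA uint8 raster.

    Valid cells are colored by max-normalized intensity (the largest valid
    value maps to the top of the colormap); each cell becomes an
    ``upsample`` x ``upsample`` nearest-neighbor block.  Deterministic for
    fixed inputs.
    """
    top = grid.max_valid()
    vals = grid.values.copy()
    if config.scaling == "log":
        positive = vals[grid.valid & (grid.values > 0)]
        floor = positive.min() if positive.size else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = (np.log10(np.maximum(vals, floor)) - np.log10(floor)) / max(
                np.log10(top) - np.log10(floor), 1e-30
            )
    else:
        norm = vals / top if top > 0 else np.zeros_like(vals)
    norm = np.clip(np.nan_to_num(norm, nan=0.0), 0.0, 1.0)

    cmap = colormaps[config.colormap]
    rgba = (cmap(norm) * 255).astype(np.uint8)
    if config.invalid_policy == "transparent":
        rgba[~grid.valid] = (0, 0, 0, 0)
    else:
        rgba[~grid.valid] = (cmap(0.0) * np.array([255, 255, 255, 255])).astype(np.uint8)
    k = config.upsample
    if k > 1:
        rgba = np.kron(rgba, np.ones((k, k, 1), dtype=np.uint8))
    return rgba


def save_png(raster: np.ndarray, path) -> None:
    Image.fromarray(raster, mode="RGBA" if raster.shape[2] == 4 else "RGB").save(path)


def overlay(
    rendered: np.ndarray,
    grid_matrix: SectionMatrix,
    photo: SectionPhoto,
    alpha: float = 0.7,
) -> np.ndarray:
    """Alpha-blend a rendered grid into the photo's pixel frame.

    The rendering is resampled (nearest neighbor) into photo coordinates
    via the photo's mm->pixel transform and the plate geometry of the
    section matrix.  ``alpha`` 0 returns the photo unchanged; 1 paints the
    rendering fully opaque wherever it lands.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    fmt = grid_matrix.format
    r0, c0 = grid_matrix.window_origin
    H, W = photo.image.shape[:2]
    out = photo.image[:, :, :3].astype(float).copy()

    # grid-cell extent in mm, then in photo pixels
    x0 = fmt.a1_offset[0] + (c0 - 0.5) * fmt.pitch
    y0 = fmt.a1_offset[1] + (r0 - 0.5) * fmt.pitch
    nrows, ncols = grid_matrix.shape
    rh, rw = rendered.shape[:2]

    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    mm_x = (xs - photo.offset_px[0]) / photo.px_per_mm
    mm_y = (ys - photo.offset_px[1]) / photo.px_per_mm
    fx = (mm_x - x0) / (ncols * fmt.pitch)  # fractional position inside window
    fy = (mm_y - y0) / (nrows * fmt.pitch)
    inside = (fx >= 0) & (fx < 1) & (fy >= 0) & (fy < 1)
    if not inside.any():
        raise ValueError("registration transform maps the grid outside the photo")

    px = np.clip((fx * rw).astype(int), 0, rw - 1)
    py = np.clip((fy * rh).astype(int), 0, rh - 1)
    src = rendered[py, px]  # (H, W, 4)
    cover = inside & (src[:, :, 3] > 0) if rendered.shape[2] == 4 else inside
    w = alpha * (src[:, :, 3:4] / 255.0 if rendered.shape[2] == 4 else 1.0)
    blended = (1 - w) * out + w * src[:, :, :3]
    out[cover] = blended[cover]
    return out.astype(np.uint8)


def export_grid(grid: ValueGrid, path, format: str = "tsv") -> None:
    """Write a grid as TSV (row, col, value, valid) or an Analyze 7.5 pair.

    Invalid cells are encoded as NaN and survive the TSV round-trip.  The
    Analyze export (``.hdr`` + ``.img``, little-endian float32) targets
    imaging viewers; dimensions equal the grid window.
    """
    if format == "tsv":
        rows = []
        for r in range(grid.shape[0]):
            for c in range(grid.shape[1]):
                rows.append(
                    (r, c, grid.values[r, c], int(grid.valid[r, c]))
                )
        df = pd.DataFrame(rows, columns=["row", "col", "value", "valid"])
        df.to_csv(path, sep="\t", index=False, na_rep="NaN")
    elif format == "analyze":
        import nibabel as nib

        data = grid.values.astype("<f4")[:, :, np.newaxis]
        img = nib.AnalyzeImage(data, affine=None)
        img.header.set_data_dtype(np.float32)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_grid_tsv(path) -> ValueGrid:
    df = pd.read_csv(path, sep="\t")
    nrows = int(df["row"].max()) + 1
    ncols = int(df["col"].max()) + 1
    values = np.full((nrows, ncols), np.nan)
    valid = np.zeros((nrows, ncols), dtype=bool)
    for _, row in df.iterrows():
        r, c = int(row["row"]), int(row["col"])
        values[r, c] = row["value"]
        valid[r, c] = bool(row["valid"])
    return ValueGrid(values, valid)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
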