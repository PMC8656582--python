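"""Chip coordinate frame: the microwell grid every image is interpreted in.

The chip is a regular lattice of microwells etched into an 8 x 8 mm active
area.  Each well has a pore in its bottom through which secreted protein
reaches the capture membrane, so the membrane spot pattern and the cell
images share one coordinate frame.  Continuous coordinates are micrometres
with the origin at the chip's top-left corner; x increases along columns,
y along rows.  Well ids are row-major and 0-based.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["ChipGeometry", "GeometryError", "well_centers", "map_point_to_well"]


class GeometryError(ValueError):
    """A chip geometry violates one of its invariants."""


@dataclass(frozen=True)
class ChipGeometry:
    """Physical layout of the microwell chip and its imaging raster.

    Defaults describe an 80 x 80 grid (6400 wells) on an 8 x 8 mm active
    area at 100 um pitch, imaged as a 10 x 10 tile mosaic at 2.5 um/px.
    The commercial chip's exact pitch is not published; 100 um is the
    square factorisation of 8 mm / 80 and the package's working preset.
    """

    n_rows: int = 80
    n_cols: int = 80
    pitch_um: float = 100.0
    pore_diameter_um: float = 5.0
    active_area_mm: tuple[float, float] = (8.0, 8.0)
    pixel_size_um: float = 2.5
    tile_grid: tuple[int, int] = (10, 10)
    spot_roi_radius_um: float = 35.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("n_rows and n_cols must be positive")
        if self.pitch_um <= 0 or self.pixel_size_um <= 0:
            raise GeometryError("pitch_um and pixel_size_um must be positive")
        width_um = self.active_area_mm[0] * 1000.0
        height_um = self.active_area_mm[1] * 1000.0
        if self.pitch_um * self.n_cols > width_um + 1e-9:
            raise GeometryError(
                f"pitch_um * n_cols = {self.pitch_um * self.n_cols} um exceeds "
                f"active width {width_um} um"
            )
        if self.pitch_um * self.n_rows > height_um + 1e-9:
            raise GeometryError(
                f"pitch_um * n_rows = {self.pitch_um * self.n_rows} um exceeds "
                f"active height {height_um} um"
            )
        if not self.spot_roi_radius_um < self.pitch_um / 2:
            raise GeometryError(
                f"spot_roi_radius_um = {self.spot_roi_radius_um} must be below "
                f"pitch_um / 2 = {self.pitch_um / 2} so adjacent ROIs never overlap"
            )

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def image_shape(self) -> tuple[int, int]:
        """Pixel dimensions of the full-chip mosaic (rows, cols)."""
        ny = int(round(self.n_rows * self.pitch_um / self.pixel_size_um))
        nx = int(round(self.n_cols * self.pitch_um / self.pixel_size_um))
        return ny, nx

    def to_dict(self) -> dict:
        d = asdict(self)
        d["active_area_mm"] = list(self.active_area_mm)
        d["tile_grid"] = list(self.tile_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChipGeometry":
        d = dict(d)
        if "active_area_mm" in d:
            d["active_area_mm"] = tuple(d["active_area_mm"])
        if "tile_grid" in d:
            d["tile_grid"] = tuple(d["tile_grid"])
        return cls(**d)


def well_centers(geometry: ChipGeometry) -> np.ndarray:
    """Centers of every well as a structured lattice.

    Returns a float array of shape (n_wells, 4) with columns
    (well_id, row, col, x_um, y_um) -- well_id = row * n_cols + col,
    center of well (0, 0) at (pitch/2, pitch/2).
    """
    rows, cols = np.meshgrid(
        np.arange(geometry.n_rows), np.arange(geometry.n_cols), indexing="ij"
    )
    rows = rows.ravel()
    cols = cols.ravel()
    x = (cols + 0.5) * geometry.pitch_um
    y = (rows + 0.5) * geometry.pitch_um
    ids = rows * geometry.n_cols + cols
    return np.column_stack([ids, rows, cols, x, y]).astype(float)


def well_center_xy(geometry: ChipGeometry) -> np.ndarray:
    """(n_wells, 2) array of (x_um, y_um) centers ordered by well_id."""
    return well_centers(geometry)[:, 3:5]


def map_point_to_well(
    geometry: ChipGeometry,
    x_um: float | np.ndarray,
    y_um: float | np.ndarray,
    tolerance_um: float | None = None,
) -> np.ndarray:
    """Map chip-frame points to the nearest well within a tolerance.

    Returns well ids as an int array (-1 where no well center lies within
    ``tolerance_um``).  Scalar inputs yield a 0-d array; use ``int()`` or
    ``.item()``.  ``tolerance_um`` defaults to pitch/2 and may not exceed it
    (beyond that the nearest center is ambiguous at well boundaries).
    """
    if tolerance_um is None:
        tolerance_um = geometry.pitch_um / 2
    if tolerance_um > geometry.pitch_um / 2 + 1e-9:
        raise GeometryError("tolerance_um must be <= pitch_um / 2")
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    col = np.round(x / geometry.pitch_um - 0.5).astype(int)
    row = np.round(y / geometry.pitch_um - 0.5).astype(int)
    col_c = np.clip(col, 0, geometry.n_cols - 1)
    row_c = np.clip(row, 0, geometry.n_rows - 1)
    cx = (col_c + 0.5) * geometry.pitch_um
    cy = (row_c + 0.5) * geometry.pitch_um
    dist = np.hypot(x - cx, y - cy)
    ids = row_c * geometry.n_cols + col_c
    return np.where(dist <= tolerance_um, ids, -1)
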