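"""Environmental gradients from a categorical land-cover grid.

Three site-level variables are derived from an eight-class cover raster
within a circular buffer (250 m radius in the study design):

* open green area — proportion of the ``open_green`` class;
* impervious surface — summed proportion of buildings, roads, and other
  paved surfaces;
* edge density — total length of boundaries between differing cover
  classes divided by buffer area (m/m2). Adjacency is 4-neighbourhood and
  only interior edges count: a pair of mask cells with different classes
  contributes one cell edge, while the buffer outline itself does not.

The raster format is the plain-text ESRI ASCII grid; cells belong to the
buffer when their centers lie within the radius (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SiteRecord, normalize_ugs

__all__ = [
    "CoverClass",
    "CoverGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "buffer_mask",
    "class_proportions",
    "edge_density",
    "sites_from_raster",
]

#: Eight-class legend; codes are the raster's integer values.
COVER_CLASSES = {
    1: "forest",
    2: "open_green",
    3: "bare_soil",
    4: "water",
    5: "buildings",
    6: "roads",
    7: "other_paved",
    8: "agriculture",
}
_NAME_TO_CODE = {v: k for k, v in COVER_CLASSES.items()}
IMPERVIOUS_CLASSES = ("buildings", "roads", "other_paved")


class CoverClass:
    """Namespace of legend codes (CoverClass.BUILDINGS == 5 etc.)."""

    FOREST, OPEN_GREEN, BARE_SOIL, WATER, BUILDINGS, ROADS, OTHER_PAVED, AGRICULTURE = range(1, 9)


@dataclass(frozen=True)
class CoverGrid:
    """A rectangular grid of cover-class codes.

    ``origin`` is the (x, y) coordinate of the center of cell (row 0,
    col 0), which is the grid's top-left cell; rows advance toward smaller
    y, matching the ASCII-grid row order.
    """

    cells: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=int)
        if cells.ndim != 2:
            raise ValueError("cells must be 2-D")
        unknown = set(np.unique(cells)) - set(COVER_CLASSES)
        if unknown:
            raise ValueError(f"unknown cover codes {sorted(unknown)}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "cells", cells)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped like cells."""
        nrows, ncols = self.cells.shape
        x0, y0 = self.origin
        xs = x0 + np.arange(ncols) * self.cell_size
        ys = y0 - np.arange(nrows) * self.cell_size
        return np.meshgrid(xs, ys)


def read_ascii_grid(path: str | Path) -> CoverGrid:
    """Read an ESRI ASCII grid (.asc) of integer class codes."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        cells = np.loadtxt(fh, dtype=int, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key!r}")
    if cells.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape {cells.shape} does not match header")
    size = header["cellsize"]
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    # top-left cell center from the lower-left corner
    origin = (xll + size / 2, yll + size * (cells.shape[0] - 0.5))
    return CoverGrid(cells=cells, cell_size=size, origin=origin)


def write_ascii_grid(grid: CoverGrid, path: str | Path) -> Path:
    path = Path(path)
    nrows, ncols = grid.cells.shape
    xll = grid.origin[0] - grid.cell_size / 2
    yll = grid.origin[1] - grid.cell_size * (nrows - 0.5)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        np.savetxt(fh, grid.cells, fmt="%d")
    return path


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def buffer_mask(grid: CoverGrid, center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of cells whose centers lie within radius (inclusive)."""
    cx, cy = center
    xs, ys = grid.cell_centers()
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    if not mask.any():
        raise ValueError(f"buffer at {center} with radius {radius} contains no cell center")
    return mask


def class_proportions(grid: CoverGrid, mask: np.ndarray) -> dict[str, float]:
    """Per-class area fractions within the mask, plus the impervious sum."""
    if not mask.any():
        raise ValueError("empty mask")
    values = grid.cells[mask]
    total = values.size
    props = {name: float(np.count_nonzero(values == code) / total) for code, name in COVER_CLASSES.items()}
    props["impervious"] = sum(props[c] for c in IMPERVIOUS_CLASSES)
    return props


def edge_density(grid: CoverGrid, mask: np.ndarray) -> float:
    """Class-boundary length per unit area inside the mask (m per m2)."""
    if not mask.any():
        raise ValueError("empty mask")
    cells = grid.cells
    s = grid.cell_size
    horiz = mask[:, :-1] & mask[:, 1:] & (cells[:, :-1] != cells[:, 1:])
    vert = mask[:-1, :] & mask[1:, :] & (cells[:-1, :] != cells[1:, :])
    edge_len = (int(horiz.sum()) + int(vert.sum())) * s
    area = int(mask.sum()) * s * s
    return edge_len / area


def sites_from_raster(
    grid: CoverGrid,
    coords: pd.DataFrame,
    radius: float = 250.0,
) -> list[SiteRecord]:
    """Compute the three environmental variables for each site.

    ``coords`` needs columns site_id, ugs_type, x, y. The output is
    SiteRecord-shaped, so it feeds straight back into the pipeline.
    """
    for col in ("site_id", "ugs_type", "x", "y"):
        if col not in coords.columns:
            raise ValueError(f"coordinates table missing column {col!r}")
    records = []
    for row in coords.itertuples(index=False):
        mask = buffer_mask(grid, (float(row.x), float(row.y)), radius)
        props = class_proportions(grid, mask)
        records.append(
            SiteRecord(
                site_id=str(row.site_id),
                ugs_type=normalize_ugs(row.ugs_type),
                open_green=props["open_green"],
                impervious=props["impervious"],
                edge_density=edge_density(grid, mask),
            )
        )
    return records
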