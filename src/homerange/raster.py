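"""Template-raster geometry and lightweight raster I/O.

A :class:`TemplateRaster` fixes the grid (extent, square cell size, CRS) on
which utilization distributions are evaluated. Grids are stored as numpy
arrays indexed ``[row, col]`` with row 0 at the **south** (bottom) edge;
writers flip to the top-down order the file formats expect.

Two on-disk formats are supported: ESRI ASCII grid (``.asc``, plain text,
self-describing geometry) and single-band float TIFF (``.tif``) with a JSON
sidecar (``<path>.geo.json``) carrying extent and EPSG code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .errors import DomainError

__all__ = ["TemplateRaster", "read_raster", "write_raster"]


@dataclass(frozen=True)
class TemplateRaster:
    """Grid geometry: extent in meters, square cells, EPSG code."""

    xmin: float
    ymin: float
    ncol: int
    nrow: int
    cell_size: float
    crs: int | None = None

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncol * self.cell_size

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrow * self.cell_size

    @classmethod
    def from_extent(cls, xmin, xmax, ymin, ymax, ncol=200, crs=None) -> "TemplateRaster":
        """Square-cell grid covering the extent with ``ncol`` columns.

        The cell size is ``(xmax - xmin)/ncol``; the number of rows is the
        smallest count covering the y-span, so ``ymax`` may grow slightly.
        """
        width = float(xmax) - float(xmin)
        height = float(ymax) - float(ymin)
        if width <= 0 or height <= 0:
            raise DomainError("template raster extent must have positive span")
        cell = width / int(ncol)
        nrow = max(1, int(np.ceil(height / cell - 1e-9)))
        return cls(float(xmin), float(ymin), int(ncol), nrow, cell, crs)

    @property
    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.ncol) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.ymin + (np.arange(self.nrow) + 0.5) * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrow, self.ncol)

    def contains(self, x, y) -> np.ndarray:
        return (
            (np.asarray(x) >= self.xmin)
            & (np.asarray(x) <= self.xmax)
            & (np.asarray(y) >= self.ymin)
            & (np.asarray(y) <= self.ymax)
        )

    def centers_covered_by(self, geom) -> np.ndarray:
        """Boolean mask of cells whose centers lie in ``geom`` (boundary inclusive)."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        pts = shapely.points(xx.ravel(), yy.ravel())
        mask = shapely.covers(geom, pts)
        return mask.reshape(self.shape)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing the points."""
        j = np.clip(((np.asarray(x) - self.xmin) / self.cell_size).astype(int), 0, self.ncol - 1)
        i = np.clip(((np.asarray(y) - self.ymin) / self.cell_size).astype(int), 0, self.nrow - 1)
        return i, j


def write_raster(grid: np.ndarray, trast: TemplateRaster, path) -> None:
    """Write a single-band raster as ``.asc`` (text) or ``.tif`` (+ sidecar)."""
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    if grid.shape != trast.shape:
        raise DomainError(f"grid shape {grid.shape} != template shape {trast.shape}")
    if path.suffix.lower() == ".asc":
        with open(path, "w") as fh:
            fh.write(
                f"ncols {trast.ncol}\nnrows {trast.nrow}\n"
                f"xllcorner {trast.xmin!r}\nyllcorner {trast.ymin!r}\n"
                f"cellsize {trast.cell_size!r}\nNODATA_value -9999\n"
            )
            np.savetxt(fh, grid[::-1], fmt="%.17g")
        if trast.crs is not None:
            with open(path.with_suffix(".prj.json"), "w") as fh:
                json.dump({"epsg": trast.crs}, fh)
        return
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, grid[::-1].astype(np.float64))
        with open(str(path) + ".geo.json", "w") as fh:
            json.dump(
                {
                    "xmin": trast.xmin,
                    "ymin": trast.ymin,
                    "ncol": trast.ncol,
                    "nrow": trast.nrow,
                    "cell_size": trast.cell_size,
                    "epsg": trast.crs,
                },
                fh,
            )
        return
    raise ValueError(f"unsupported raster extension {path.suffix!r} (use .asc or .tif)")


def read_raster(path, crs: int | None = None) -> tuple[np.ndarray, TemplateRaster]:
    """Read a raster written by :func:`write_raster`; returns (grid, template)."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        header = {}
        with open(path) as fh:
            for _ in range(6):
                k, v = fh.readline().split()
                header[k.lower()] = float(v)
            grid = np.loadtxt(fh)
        grid = np.atleast_2d(grid)[::-1]
        prj = path.with_suffix(".prj.json")
        if crs is None and prj.exists():
            with open(prj) as fh:
                crs = json.load(fh).get("epsg")
        trast = TemplateRaster(
            header["xllcorner"],
            header["yllcorner"],
            int(header["ncols"]),
            int(header["nrows"]),
            header["cellsize"],
            crs,
        )
        return grid, trast
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = np.asarray(tifffile.imread(path), dtype=float)[::-1]
        with open(str(path) + ".geo.json") as fh:
            meta = json.load(fh)
        trast = TemplateRaster(
            meta["xmin"],
            meta["ymin"],
            int(meta["ncol"]),
            int(meta["nrow"]),
            meta["cell_size"],
            crs if crs is not None else meta.get("epsg"),
        )
        return grid, trast
    raise ValueError(f"unsupported raster extension {path.suffix!r}")
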