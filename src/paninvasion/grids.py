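"""Raster grid containers and ESRI ASCII grid I/O.

All grids in this package follow the ESRI ASCII convention: pixel-centred
values, row 0 is the northernmost row, the origin is the top-left *corner*
of the top-left pixel, and the cell size is in decimal degrees. Geometry
comparisons are exact on ``(origin, cellsize, shape)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grid",
    "CovariateStack",
    "SuitabilityGrid",
    "RegionGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "rasterize_rectangles",
]

NODATA_DEFAULT = -9999.0


@dataclass
class Grid:
    """A single 2-D raster.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks nodata in memory.
    origin : (float, float)
        ``(west, north)``: lon/lat of the top-left corner of pixel (0, 0).
    cellsize : float
        Cell edge length in decimal degrees (square cells).
    """

    values: np.ndarray
    origin: tuple[float, float]
    cellsize: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[tuple[float, float], float, tuple[int, int]]:
        return (self.origin, self.cellsize, self.shape)

    def same_geometry(self, other: "Grid") -> bool:
        return self.geometry() == other.geometry()

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat arrays of every pixel centre (each shape ``(nrows, ncols)``)."""
        west, north = self.origin
        nrows, ncols = self.shape
        lons = west + (np.arange(ncols) + 0.5) * self.cellsize
        lats = north - (np.arange(nrows) + 0.5) * self.cellsize
        return np.meshgrid(lons, lats)

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point.

        Points on a cell boundary belong to the higher-index cell
        (plain ``floor`` of the offset divided by the cell size).
        """
        west, north = self.origin
        col = np.floor((np.asarray(lon) - west) / self.cellsize).astype(int)
        row = np.floor((north - np.asarray(lat)) / self.cellsize).astype(int)
        return row, col


@dataclass
class SuitabilityGrid(Grid):
    """Establishment suitability surface; every valid pixel lies in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        valid = self.values[~np.isnan(self.values)]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass
class RegionGrid:
    """Raster of region labels; None marks nodata.

    Stored as an object array of region-identifier strings so that zonal
    statistics can group pixels by region without a lookup table.
    """

    labels: np.ndarray
    origin: tuple[float, float]
    cellsize: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("region labels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def geometry(self) -> tuple[tuple[float, float], float, tuple[int, int]]:
        return (self.origin, self.cellsize, self.shape)


@dataclass
class CovariateStack:
    """Named, geometry-aligned environmental covariate rasters."""

    names: list[str]
    grids: list[Grid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.grids):
            raise ValueError("names and grids must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        if not self.grids:
            raise ValueError("stack needs at least one covariate")
        first = self.grids[0]
        for g in self.grids[1:]:
            if not first.same_geometry(g):
                raise ValueError("all covariates must share geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[0].shape

    @property
    def origin(self) -> tuple[float, float]:
        return self.grids[0].origin

    @property
    def cellsize(self) -> float:
        return self.grids[0].cellsize

    def __getitem__(self, name: str) -> Grid:
        return self.grids[self.names.index(name)]

    def as_array(self) -> np.ndarray:
        """Stack values into shape ``(n_covariates, nrows, ncols)``."""
        return np.stack([g.values for g in self.grids])

    def valid_mask(self) -> np.ndarray:
        """Pixels where every covariate has data."""
        return ~np.isnan(self.as_array()).any(axis=0)

    def subset(self, names: Sequence[str]) -> "CovariateStack":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"covariates not in stack: {missing}")
        return CovariateStack(list(names), [self[n] for n in names])


def read_ascii_grid(path: str | Path | io.TextIOBase) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    Header keys ``ncols``, ``nrows``, ``xllcorner``, ``yllcorner``,
    ``cellsize`` are required; ``NODATA_value`` is optional. Nodata cells
    become NaN.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= header.keys():
        raise ValueError(f"ASCII grid header missing keys: {sorted(required - header.keys())}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(
            f"ASCII grid body has {values.size} values, expected {nrows * ncols}"
        )
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    west = header["xllcorner"]
    north = header["yllcorner"] + nrows * header["cellsize"]
    return Grid(values, (west, north), header["cellsize"])


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = NODATA_DEFAULT) -> None:
    """Write a grid as ESRI ASCII at full float precision (round-trip exact)."""
    west, north = grid.origin
    nrows, ncols = grid.shape
    yll = north - nrows * grid.cellsize
    out = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {west!r}",
        f"yllcorner {yll!r}",
        f"cellsize {grid.cellsize!r}",
        f"NODATA_value {nodata!r}",
    ]
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    for row in vals:
        out.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(out) + "\n")


def rasterize_rectangles(
    rectangles: Iterable[tuple[str, float, float, float, float]],
    template: Grid,
) -> RegionGrid:
    """Rasterize ``(region, west, south, east, north)`` boxes onto a template grid.

    A helper for building RegionGrid fixtures without a geometry engine: a
    pixel belongs to a rectangle if its centre lies inside; later rectangles
    overwrite earlier ones.
    """
    labels = np.full(template.shape, None, dtype=object)
    lon, lat = template.pixel_centers()
    for region, west, south, east, north in rectangles:
        inside = (lon >= west) & (lon < east) & (lat > south) & (lat <= north)
        labels[inside] = region
    return RegionGrid(labels, template.origin, template.cellsize)
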