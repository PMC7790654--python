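"""Georeferenced cell lattices and named raster stacks.

A :class:`GeoGrid` is a regular longitude/latitude lattice (WGS84 decimal
degrees) holding one real value per cell, with ``NaN`` marking nodata. Row 0
is the northernmost row; ``origin_lon``/``origin_lat`` locate the *outer*
west/north edge of the grid. All layers of a :class:`RasterStack` share one
geometry, which is what lets values be extracted, modelled and projected
cell-for-cell across layers and time periods.

Rasters are serialized as ESRI ASCII grids (plain text, one file per layer),
the package's native on-disk format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

NODATA = -9999.0
EARTH_RADIUS_KM = 6371.0


@dataclass
class GeoGrid:
    """A single-band raster on a regular WGS84 degree lattice."""

    values: np.ndarray          # 2-D float array, NaN = nodata; row 0 = north
    origin_lon: float           # west edge of column 0, degrees
    origin_lat: float           # north edge of row 0, degrees
    cell_size: float            # degrees, square cells

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GeoGrid values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return np.isfinite(self.values)

    @property
    def n_unmasked(self) -> int:
        return int(self.mask.sum())

    def same_geometry(self, other: "GeoGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=tol)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12, abs_tol=tol)
        )

    def cell_center(self, row, col):
        """Longitude/latitude of cell centers (vectorized)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_index(self, lon, lat):
        """Row/column of the cell containing each point.

        Points outside the lattice get index -1 in both coordinates.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def unmasked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray) -> "GeoGrid":
        """A new grid with the same geometry and different values."""
        return GeoGrid(np.asarray(values, dtype=float), self.origin_lon,
                       self.origin_lat, self.cell_size)

    # -- cell areas ---------------------------------------------------------
    def cell_areas_km2(self) -> np.ndarray:
        """Spherical area of every cell in km^2 (row-wise constant).

        Uses the exact spherical quadrilateral between the cell's *edge*
        latitudes: A = R^2 * dlam * (sin(lat_top) - sin(lat_bottom)).
        """
        rows = np.arange(self.n_rows)
        top = np.radians(self.origin_lat - rows * self.cell_size)
        bottom = np.radians(self.origin_lat - (rows + 1) * self.cell_size)
        dlam = math.radians(self.cell_size)
        row_area = EARTH_RADIUS_KM ** 2 * dlam * (np.sin(top) - np.sin(bottom))
        return np.repeat(row_area[:, None], self.n_cols, axis=1)

    # -- I/O ----------------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str = "%.9g") -> Path:
        """Write the grid as an ESRI ASCII raster."""
        path = Path(path)
        vals = np.where(self.mask, self.values, NODATA)
        yll = self.origin_lat - self.n_rows * self.cell_size
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_lon!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {NODATA:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt=fmt)
        return path

    @classmethod
    def read_ascii(cls, path: str | Path) -> "GeoGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh, dtype=float)
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value", NODATA)
        values[values == nodata] = np.nan
        n_rows = int(header["nrows"])
        cell = header["cellsize"]
        return cls(
            values=values,
            origin_lon=header["xllcorner"],
            origin_lat=header["yllcorner"] + n_rows * cell,
            cell_size=cell,
        )


@dataclass
class RasterStack:
    """Ordered, name-keyed collection of :class:`GeoGrid` layers on one grid."""

    layers: dict[str, GeoGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise ValueError("all layers of a RasterStack must share the grid geometry")

    @property
    def names(self) -> list[str]:
        return list(self.layers.keys())

    @property
    def grid(self) -> GeoGrid:
        """The reference geometry (first layer)."""
        if not self.layers:
            raise ValueError("empty stack has no geometry")
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> GeoGrid:
        return self.layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def add(self, name: str, grid: GeoGrid) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self.layers and not grid.same_geometry(self.grid):
            raise ValueError("layer geometry mismatch")
        self.layers[name] = grid

    def shared_mask(self) -> np.ndarray:
        """Cells unmasked in every layer."""
        mask = np.ones(self.grid.values.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.mask
        return mask

    def to_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Layer values at the given cells, shape (n_cells, n_layers)."""
        out = np.empty((len(rows), len(self.layers)), dtype=float)
        for j, g in enumerate(self.layers.values()):
            out[:, j] = g.values[rows, cols]
        return out

    def cell_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, matrix) over the shared unmasked cells, row-major order."""
        mask = self.shared_mask()
        rows, cols = np.nonzero(mask)
        return rows, cols, self.to_matrix(rows, cols)

    # -- I/O ----------------------------------------------------------------
    def write_dir(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, g in self.layers.items():
            g.write_ascii(directory / f"{name}.asc")
        return directory

    @classmethod
    def read_dir(cls, directory: str | Path, names: list[str] | None = None) -> "RasterStack":
        """Read every ``*.asc`` in a directory; layer name = file stem."""
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if names is not None:
            by_stem = {p.stem: p for p in paths}
            missing = [n for n in names if n not in by_stem]
            if missing:
                raise FileNotFoundError(f"missing raster layer(s): {missing} in {directory}")
            paths = [by_stem[n] for n in names]
        if not paths:
            raise FileNotFoundError(f"no .asc rasters found in {directory}")
        stack = cls()
        for p in paths:
            stack.add(p.stem, GeoGrid.read_ascii(p))
        return stack

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, GeoGrid]) -> "RasterStack":
        stack = cls()
        for name, g in mapping.items():
            stack.add(name, g)
        return stack
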