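"""Gridded-layer containers and plain-text raster I/O.

Layers live on a shared geographic grid (WGS84-style lon/lat degrees), rows
running north to south, cell-center registration for all sampling.  On-disk
format is the ESRI ASCII grid (``.asc``): a self-describing, line-oriented
text format readable by every GIS.  Values are written with 17 significant
digits so float64 rasters round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

NODATA_DEFAULT = -9999.0

#: Table-style variable codes expected in a fully assembled stack: the 19
#: bioclimatic variables plus seven terrain variables derived from the DEM.
BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))
TERRAIN_NAMES = ("Aspect", "DEM", "Flowdir", "Slope", "TPI", "TRI", "Roughness")
STACK_NAMES = BIOCLIM_NAMES + TERRAIN_NAMES


@dataclass(frozen=True)
class Grid:
    """Geometry of a north-up geographic raster.

    ``origin_lon``/``origin_lat`` are the outer edge of the north-west cell;
    row 0 is the northernmost row.  ``cell_size`` is in decimal degrees.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    crs_note: str = "geographic lon/lat (WGS84-style degrees)"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (lon, lat) of all cell centers, shape (n_rows, n_cols)."""
        lons = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lats = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lons, lats)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (nearest-cell rule).

        Raises ``ValueError`` for points outside the grid.
        """
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid")
        return row, col


@dataclass
class Layer:
    """A single named variable on a grid, with an explicit nodata mask."""

    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} != grid {self.grid.shape}"
            )
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError(f"layer {self.name!r}: non-finite values outside nodata mask")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def masked(self) -> np.ndarray:
        """Values with nodata as NaN (copy)."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def copy(self, name: str | None = None) -> "Layer":
        return Layer(self.grid, self.values.copy(), self.nodata_mask.copy(),
                     self.name if name is None else name)


class EnvStack:
    """Named set of co-registered layers plus optional monthly climate.

    The shared nodata mask is the union of the member masks: a cell is usable
    only where every layer has data.
    """

    def __init__(self, grid: Grid, layers: Mapping[str, Layer] | None = None,
                 monthly: Mapping[str, list[Layer]] | None = None):
        self.grid = grid
        self.layers: dict[str, Layer] = {}
        self.monthly: dict[str, list[Layer]] = {}
        for name, layer in (layers or {}).items():
            self.add(name, layer)
        for key, series in (monthly or {}).items():
            self.add_monthly(key, series)

    def add(self, name: str, layer: Layer) -> None:
        if layer.grid != self.grid:
            raise ValueError(
                f"layer {name!r} grid mismatch; resample explicitly before stacking"
            )
        layer = layer.copy(name=name)
        self.layers[name] = layer

    def add_monthly(self, key: str, series: Iterable[Layer]) -> None:
        series = list(series)
        if len(series) != 12:
            raise ValueError(f"monthly series {key!r} must have 12 layers")
        for lyr in series:
            if lyr.grid != self.grid:
                raise ValueError(f"monthly series {key!r}: grid mismatch")
        self.monthly[key] = series

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> Layer:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"layer {name!r} missing from stack; have {sorted(self.layers)}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shared_mask(self) -> np.ndarray:
        """Union of nodata masks over all layers (True = unusable)."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask |= layer.nodata_mask
        for series in self.monthly.values():
            for lyr in series:
                mask |= lyr.nodata_mask
        return mask

    def is_complete(self) -> bool:
        """True when all 26 standard variable codes are present."""
        return all(name in self.layers for name in STACK_NAMES)

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing layers: {missing}")

    def to_matrix(self, names: Iterable[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_cells, n_vars) matrix over shared-valid cells and the flat valid mask."""
        names = list(names) if names is not None else self.names
        self.require(names)
        valid = ~self.shared_mask
        cols = [self.layers[n].values[valid] for n in names]
        return np.column_stack(cols), valid


@dataclass(frozen=True)
class StudyExtent:
    """Rectangular accessible area (M) in degrees."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("extent must satisfy lat_min < lat_max and lon_min < lon_max")

    def contains(self, lon, lat):
        return (self.lon_min <= lon) & (lon <= self.lon_max) & \
               (self.lat_min <= lat) & (lat <= self.lat_max)


# ---------------------------------------------------------------------------
# ASCII-grid I/O

def write_raster(layer: Layer, path: str | Path, nodata: float = NODATA_DEFAULT) -> Path:
    """Write a layer as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    g = layer.grid
    yll = g.origin_lat - g.n_rows * g.cell_size
    vals = layer.values.copy()
    vals[layer.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_lon!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_raster(path: str | Path, name: str | None = None) -> Layer:
    """Read an ESRI ASCII grid into a Layer.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    malformed headers (the six georeferencing keys are mandatory).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                try:
                    rows.append(np.array([float(p) for p in parts]))
                except ValueError as exc:
                    raise ValueError(f"{path}: unreadable data line: {line!r}") from exc
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise ValueError(f"{path}: missing georeferencing keys {required - set(header)}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    values = np.vstack(rows)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != header ({n_rows}, {n_cols})")
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    mask = values == nodata
    cell = header["cellsize"]
    grid = Grid(n_rows, n_cols, header["xllcorner"],
                header["yllcorner"] + n_rows * cell, cell)
    return Layer(grid, values, mask, name or path.stem)


# ---------------------------------------------------------------------------
# Cropping

def crop_layer(layer: Layer, extent: StudyExtent) -> Layer:
    """Keep exactly the cells whose centers fall inside the extent."""
    g = layer.grid
    lon, lat = g.cell_centers()
    inside = extent.contains(lon, lat)
    if not inside.any():
        raise ValueError("extent does not intersect the grid")
    rows = np.where(inside.any(axis=1))[0]
    cols = np.where(inside.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    new_grid = Grid(r1 - r0, c1 - c0,
                    g.origin_lon + c0 * g.cell_size,
                    g.origin_lat - r0 * g.cell_size,
                    g.cell_size, g.crs_note)
    return Layer(new_grid, layer.values[r0:r1, c0:c1].copy(),
                 layer.nodata_mask[r0:r1, c0:c1].copy(), layer.name)


def crop_to_extent(stack: EnvStack, extent: StudyExtent) -> EnvStack:
    """Crop every layer (and monthly series) of a stack to the study extent M."""
    first = next(iter(stack.layers.values()), None)
    if first is None:
        for series in stack.monthly.values():
            first = series[0]
            break
    if first is None:
        raise ValueError("cannot crop an empty stack")
    new_grid = crop_layer(first, extent).grid
    out = EnvStack(new_grid)
    for name, layer in stack.layers.items():
        out.add(name, crop_layer(layer, extent))
    for key, series in stack.monthly.items():
        out.add_monthly(key, [crop_layer(lyr, extent) for lyr in series])
    return out


def constant_layer(grid: Grid, value: float, name: str = "",
                   mask: np.ndarray | None = None) -> Layer:
    vals = np.full(grid.shape, float(value))
    m = np.zeros(grid.shape, bool) if mask is None else mask.copy()
    return Layer(grid, vals, m, name)
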