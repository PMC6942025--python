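"""Gridded climate layers: geometry, in-memory stacks, plain-text raster I/O.

A :class:`ClimateStack` holds one named raster per weather variable for a
single year (or a multi-year period) on a shared grid.  Grids follow the map
convention: the origin ``(x0, y0)`` is the *top-left* corner, x grows east,
y grows north, so row 0 is the northernmost row.  Missing cells (sea,
foreign territory) are NaN in memory and a nodata sentinel on disk.

Rasters are stored as ESRI ASCII grids (one text file per variable per
year) plus a YAML manifest mapping variables and years to files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Canonical variable set: mean temperature of spring (Mar-May), September,
#: October and December [degC]; precipitation sums of February, April and
#: June [mm]; autumn drought index (Sep-Nov average) [index units].
CANONICAL_VARIABLES = ("T13", "T09", "T10", "T12", "P02", "P04", "P06", "D15")

VARIABLE_UNITS: Mapping[str, str] = {
    "T13": "degC", "T09": "degC", "T10": "degC", "T12": "degC",
    "P02": "mm", "P04": "mm", "P06": "mm", "D15": "index",
}

DEFAULT_NODATA = -9999.0


class GridError(ValueError):
    """Raised for inconsistent grid geometries or malformed raster files."""


@dataclass(frozen=True)
class GridGeometry:
    """Planar grid: top-left corner at ``(x0, y0)``, y decreasing row-wise.

    Cells are half-open in x, ``[x0 + j*cell, x0 + (j+1)*cell)``, and
    half-open downward in y, ``(y0 - (i+1)*cell, y0 - i*cell]``, so every
    point inside the extent maps to exactly one cell.
    """

    rows: int
    cols: int
    cell_size: float
    x0: float = 0.0
    y0: float | None = None  # defaults to rows * cell_size (y >= 0 grid)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise GridError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise GridError("cell size must be positive")
        if self.y0 is None:
            object.__setattr__(self, "y0", self.rows * self.cell_size)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return (
            self.x0,
            self.x0 + self.cols * self.cell_size,
            self.y0 - self.rows * self.cell_size,
            self.y0,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return (xmin <= x < xmax) and (ymin < y <= ymax)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Nearest-cell containment; raises GridError outside the extent."""
        if not (math.isfinite(x) and math.isfinite(y)):
            raise GridError(f"non-finite coordinates ({x}, {y})")
        if not self.contains(x, y):
            raise GridError(f"point ({x}, {y}) outside grid extent {self.extent}")
        col = int((x - self.x0) // self.cell_size)
        row = int(np.ceil((self.y0 - y) / self.cell_size)) - 1
        row = min(max(row, 0), self.rows - 1)
        col = min(col, self.cols - 1)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            self.y0 - (row + 0.5) * self.cell_size,
        )


@dataclass
class ClimateStack:
    """Named rasters for one year (or period label) on a common geometry."""

    label: int | str
    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.geometry.rows, self.geometry.cols):
                raise GridError(
                    f"layer {name!r} shape {arr.shape} does not match grid "
                    f"({self.geometry.rows}, {self.geometry.cols})"
                )
            self.layers[name] = arr

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def value_at(self, variable: str, x: float, y: float) -> float:
        """Value of the cell containing (x, y); NaN on nodata cells."""
        if variable not in self.layers:
            raise GridError(f"variable {variable!r} not in stack {self.label}")
        row, col = self.geometry.cell_of(x, y)
        return float(self.layers[variable][row, col])

    def valid_mask(self, variables: Iterable[str] | None = None) -> np.ndarray:
        """Boolean mask of cells where every requested layer is finite."""
        names = list(variables) if variables is not None else self.variables
        mask = np.ones((self.geometry.rows, self.geometry.cols), dtype=bool)
        for name in names:
            if name not in self.layers:
                raise GridError(f"variable {name!r} not in stack {self.label}")
            mask &= np.isfinite(self.layers[name])
        return mask


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path: str | Path, values: np.ndarray, geometry: GridGeometry,
                     nodata: float = DEFAULT_NODATA) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != (geometry.rows, geometry.cols):
        raise GridError("array shape does not match geometry")
    out = np.where(np.isfinite(values), values, nodata)
    xmin, _, ymin, _ = geometry.extent
    header = (
        f"ncols {geometry.cols}\n"
        f"nrows {geometry.rows}\n"
        f"xllcorner {xmin!r}\n"
        f"yllcorner {ymin!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                # headers may omit NODATA_value; rewind and stop
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridError(f"{path}: missing header field {key!r}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (rows, cols):
        raise GridError(f"{path}: data shape {data.shape} != header ({rows}, {cols})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(np.isclose(data, nodata), np.nan, data)
    geom = GridGeometry(
        rows=rows, cols=cols, cell_size=header["cellsize"],
        x0=header["xllcorner"],
        y0=header["yllcorner"] + rows * header["cellsize"],
    )
    return data, geom


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Stack <-> directory of grids plus manifest


def write_stacks(stacks: Iterable[ClimateStack], out_dir: str | Path,
                 nodata: float = DEFAULT_NODATA) -> Path:
    """Write one ASCII grid per variable per stack plus a YAML manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "esri_ascii", "nodata": nodata, "stacks": {}}
    for stack in stacks:
        entry: dict[str, str] = {}
        for var, arr in stack.layers.items():
            fname = f"{stack.label}_{var}.asc"
            write_ascii_grid(out_dir / fname, arr, stack.geometry, nodata)
            entry[var] = fname
        manifest["stacks"][str(stack.label)] = entry
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_stacks(manifest_path: str | Path) -> dict[str, ClimateStack]:
    """Read every stack listed in a manifest; keys are the stack labels."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    stacks: dict[str, ClimateStack] = {}
    for label, entry in manifest["stacks"].items():
        layers: dict[str, np.ndarray] = {}
        geom: GridGeometry | None = None
        for var, fname in entry.items():
            arr, g = read_ascii_grid(base / fname)
            if geom is None:
                geom = g
            elif g != geom:
                raise GridError(f"stack {label}: layer {var} geometry differs")
            layers[var] = arr
        assert geom is not None
        try:
            key: int | str = int(label)
        except ValueError:
            key = label
        stacks[str(label)] = ClimateStack(label=key, geometry=geom, layers=layers)
    return stacks
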