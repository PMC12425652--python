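"""Aligned multi-layer raster container for environmental predictors.

A :class:`CovariateStack` holds an ordered set of co-registered grids —
continuous predictors (temperature, precipitation, slope, ...) and
categorical ones (land use) — on a regular planar grid in metres, together
with a shared nodata mask.  Row 0 is the northern (top) row, matching the
on-disk convention of the ESRI ASCII grid format used for I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Layer", "CovariateStack", "read_ascii_grid", "write_ascii_grid"]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class Layer:
    """One predictor grid.

    ``values`` is a float array of shape (n_rows, n_cols).  For categorical
    layers the cell values are integer category codes stored as floats, and
    ``codes`` enumerates the declared code set.
    """

    name: str
    kind: str
    values: np.ndarray
    codes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == CATEGORICAL:
            if self.codes is None:
                self.codes = tuple(sorted(int(c) for c in np.unique(self.values[np.isfinite(self.values)])))
            else:
                self.codes = tuple(int(c) for c in self.codes)


@dataclass
class CovariateStack:
    """Stack of aligned predictor layers on a regular metric grid.

    Parameters
    ----------
    cell_size : float
        Cell edge length in metres.
    origin : tuple of float
        (x0, y0) map coordinates of the lower-left corner of the grid.
    layers : list of Layer
        All layers share one (n_rows, n_cols) shape.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no data (shared across layers).
    """

    cell_size: float
    origin: tuple[float, float]
    layers: list[Layer]
    nodata_mask: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a CovariateStack needs at least one layer")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        shape = self.layers[0].values.shape
        for lyr in self.layers:
            if lyr.values.shape != shape:
                raise ValueError(
                    f"layer {lyr.name!r} shape {lyr.values.shape} does not match {shape}"
                )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != shape:
                raise ValueError("nodata_mask shape does not match layers")
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self._index = {n: i for i, n in enumerate(names)}

    # -- basic geometry -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.layers[0].values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.layers[0].values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where data are present."""
        return ~self.nodata_mask

    @property
    def layer_names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def layer(self, name: str) -> Layer:
        return self.layers[self._index[name]]

    def cell_index(self, x, y):
        """Map coordinates -> (row, col) integer arrays; -1 where off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        # row 0 is the top row
        row = np.floor((y0 + self.n_rows * self.cell_size - y) / self.cell_size).astype(int)
        off = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(off, -1, col)
        row = np.where(off, -1, row)
        return row, col

    def cell_center(self, row, col):
        """(row, col) -> map coordinates of the cell centre."""
        row = np.asarray(row)
        col = np.asarray(col)
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def on_valid_cell(self, x, y) -> np.ndarray:
        """True for points that land on a valid (non-nodata) cell."""
        row, col = self.cell_index(np.atleast_1d(x), np.atleast_1d(y))
        ok = (row >= 0) & (col >= 0)
        out = np.zeros_like(ok)
        out[ok] = self.valid_mask[row[ok], col[ok]]
        return out

    def extract(self, x, y, layer_names: list[str] | None = None) -> np.ndarray:
        """Per-point layer values, shape (n_points, n_layers).

        Raises ValueError naming the first offending point if any point is
        off-grid or on a nodata cell.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.cell_index(x, y)
        bad = (row < 0) | (col < 0)
        if not bad.any():
            bad = ~self.valid_mask[row, col]
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(f"point ({x[i]:g}, {y[i]:g}) is off-raster or on nodata")
        names = layer_names if layer_names is not None else self.layer_names
        return np.column_stack([self.layer(n).values[row, col] for n in names])

    # -- I/O -------------------------------------------------------------

    def write_ascii(self, directory: str | Path, nodata_value: float = -9999.0) -> None:
        """Write one ESRI ASCII grid per layer plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for lyr in self.layers:
            vals = np.where(self.nodata_mask, nodata_value, lyr.values)
            write_ascii_grid(
                directory / f"{lyr.name}.asc", vals, self.cell_size, self.origin, nodata_value
            )
        manifest = {
            "cell_size": self.cell_size,
            "origin": list(self.origin),
            "layers": [
                {"name": lyr.name, "kind": lyr.kind, "codes": list(lyr.codes) if lyr.codes else None}
                for lyr in self.layers
            ],
        }
        (directory / "stack.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read_ascii(cls, directory: str | Path) -> "CovariateStack":
        directory = Path(directory)
        manifest = json.loads((directory / "stack.json").read_text())
        layers: list[Layer] = []
        mask = None
        for entry in manifest["layers"]:
            vals, cell, origin, nodata = read_ascii_grid(directory / f"{entry['name']}.asc")
            lyr_mask = vals == nodata if nodata is not None else np.zeros(vals.shape, bool)
            vals = np.where(lyr_mask, np.nan, vals)
            mask = lyr_mask if mask is None else (mask | lyr_mask)
            codes = tuple(entry["codes"]) if entry.get("codes") else None
            layers.append(Layer(entry["name"], entry["kind"], vals, codes))
        return cls(manifest["cell_size"], tuple(manifest["origin"]), layers, mask)


def write_ascii_grid(path, values, cell_size, origin, nodata_value=-9999.0) -> None:
    """Write a single-band ESRI ASCII grid (row 0 = north)."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\n"
        f"cellsize {cell_size:.6f}\n"
        f"NODATA_value {nodata_value:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.where(np.isnan(values), nodata_value, values), fmt="%.8g")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (values, cell_size, origin, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    origin = (header["xllcorner"], header["yllcorner"])
    return values, header["cellsize"], origin, header.get("nodata_value")
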