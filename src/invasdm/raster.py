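"""Gridded raster containers and lightweight raster I/O.

A :class:`Landscape` is a stack of co-registered single-band rasters sharing
one boolean mask (True = modellable cell) and one geotransform.  Layers are
written as single-band float32 TIFFs with an explicit no-data sentinel; the
geotransform, mask and layer inventory travel in a sidecar JSON so a saved
landscape round-trips exactly.

Coordinate convention: x increases eastward, y northward; the geotransform
stores the top-left corner of the grid.  A point (x, y) belongs to the cell
whose half-open interval [edge, edge + res) contains it, and each cell is
represented by its centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA = -9999.0

__all__ = ["GridTransform", "Landscape", "NODATA"]


@dataclass(frozen=True)
class GridTransform:
    """Affine north-up geotransform: top-left corner and square cell size."""

    x0: float
    y0: float
    res: float

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        x = self.x0 + (np.asarray(col) + 0.5) * self.res
        y = self.y0 - (np.asarray(row) + 0.5) * self.res
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray):
        """Row/col of the half-open cell containing each point."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.res).astype(int)
        row = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.res).astype(int)
        return row, col

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "res": self.res}

    @classmethod
    def from_dict(cls, d: dict) -> "GridTransform":
        return cls(x0=d["x0"], y0=d["y0"], res=d["res"])


@dataclass
class Landscape:
    """Co-registered environmental layers over a masked grid.

    Parameters
    ----------
    layers
        Mapping layer name -> 2-D float array.  Off-mask cells hold
        :data:`NODATA`; on-mask values are finite.
    mask
        Boolean array, True where cells are modellable.
    transform
        Shared geotransform.
    seed
        Seed the landscape was generated from (None for loaded data).
    """

    layers: dict[str, np.ndarray]
    mask: np.ndarray
    transform: GridTransform
    seed: int | None = None
    nodata: float = NODATA
    _order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self._order = list(self.layers)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.mask.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, mask is {self.mask.shape}"
                )
            if not np.all(np.isfinite(arr[self.mask])):
                raise ValueError(f"layer {name!r} has non-finite values on the mask")
            arr = arr.copy()
            arr[~self.mask] = self.nodata
            self.layers[name] = arr

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def layer_names(self) -> list[str]:
        return list(self._order)

    @property
    def n_mask_cells(self) -> int:
        return int(self.mask.sum())

    def mask_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of all modellable cells, row-major order."""
        return np.nonzero(self.mask)

    def on_mask(self, x, y) -> np.ndarray:
        row, col = self.transform.cell_of(x, y)
        nr, nc = self.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.zeros_like(ok)
        out[ok] = self.mask[row[ok], col[ok]]
        return out

    # -- value access ---------------------------------------------------

    def values_at_cells(self, rows, cols, variables: list[str]) -> np.ndarray:
        """(n_points, n_vars) matrix of layer values at given cells."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        if not np.all(self.mask[rows, cols]):
            raise ValueError("requested cells include no-data cells")
        return np.column_stack([self.layers[v][rows, cols] for v in variables])

    def table(self, variables: list[str] | None = None):
        """Design matrix over all mask cells plus their row/col indices."""
        import pandas as pd

        variables = variables or self.layer_names
        rows, cols = self.mask_cells()
        mat = self.values_at_cells(rows, cols, variables)
        df = pd.DataFrame(mat, columns=variables)
        df.insert(0, "row", rows)
        df.insert(1, "col", cols)
        return df

    def grid_from_mask_values(self, values: np.ndarray) -> np.ndarray:
        """Scatter a vector over mask cells back onto the grid (NaN off-mask)."""
        grid = np.full(self.shape, np.nan)
        grid[self.mask] = values
        return grid

    # -- I/O -------------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._order:
            write_band(directory / f"{name}.tif", self.layers[name], self.transform,
                       nodata=self.nodata)
        meta = {
            "layers": self._order,
            "transform": self.transform.to_dict(),
            "nodata": self.nodata,
            "seed": self.seed,
            "shape": list(self.shape),
        }
        (directory / "landscape.json").write_text(json.dumps(meta, indent=2))
        tifffile.imwrite(directory / "mask.tif", self.mask.astype(np.uint8))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "Landscape":
        directory = Path(directory)
        meta = json.loads((directory / "landscape.json").read_text())
        transform = GridTransform.from_dict(meta["transform"])
        mask = tifffile.imread(directory / "mask.tif").astype(bool)
        layers = {}
        for name in meta["layers"]:
            band, _ = read_band(directory / f"{name}.tif")
            arr = band.astype(float)
            arr[~mask] = meta["nodata"]
            layers[name] = arr
        return cls(layers=layers, mask=mask, transform=transform,
                   seed=meta.get("seed"), nodata=meta["nodata"])


def write_band(path: str | Path, band: np.ndarray, transform: GridTransform,
               nodata: float = NODATA) -> Path:
    """Write one raster band as float32 TIFF with a JSON sidecar for georeference."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(band, dtype=np.float32))
    sidecar = {"transform": transform.to_dict(), "nodata": nodata}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def read_band(path: str | Path) -> tuple[np.ndarray, GridTransform]:
    path = Path(path)
    band = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return band, GridTransform.from_dict(sidecar["transform"])
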