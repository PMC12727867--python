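"""Aligned environmental raster stacks.

Grids are north-up, geographic (WGS-84 lon/lat), with NaN marking nodata.
The stack used throughout the pipeline carries eight covariates:

====================  ==============================================
``MAT``               mean annual temperature, deg C
``MAP``               mean annual precipitation, mm
``dMAT`` / ``dMAP``   projected change (2081-2100 minus 1970-2000)
``LAI``               leaf area index, m2 m-2 (may contain gaps)
``SOC``               soil organic carbon stock, upper 2 m
``plant_rich``        vascular plant species richness per 1000 m2
``animal_rich``       bird + mammal species richness
====================  ==============================================

Raster I/O uses the ESRI ASCII grid format (plain text, square cells) with a
JSON manifest mapping layer names to files and units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "CovariateStack",
    "LAYER_UNITS",
    "climate_anomaly",
    "focal_fill",
    "extract_at_points",
    "sample_background",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
]

LAYER_UNITS: dict[str, str] = {
    "MAT": "degC",
    "MAP": "mm",
    "dMAT": "degC",
    "dMAP": "mm",
    "LAI": "m2 m-2",
    "SOC": "t ha-1 (0-2 m)",
    "plant_rich": "species / 1000 m2",
    "animal_rich": "species",
}


@dataclass
class RasterGrid:
    """A single north-up geographic grid; NaN cells are nodata.

    ``x0``/``y0`` are the coordinates of the grid's north-west corner;
    ``dx``/``dy`` are positive cell sizes in degrees (rows run southward).
    """

    data: np.ndarray
    x0: float
    y0: float
    dx: float
    dy: float
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of valid (non-nodata) cells."""
        return np.isfinite(self.data)

    @property
    def lon_centers(self) -> np.ndarray:
        nx = self.shape[1]
        return self.x0 + (np.arange(nx) + 0.5) * self.dx

    @property
    def lat_centers(self) -> np.ndarray:
        ny = self.shape[0]
        return self.y0 - (np.arange(ny) + 0.5) * self.dy

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point, plus an in-extent mask.

        Index arithmetic is ``floor((lon - x0)/dx)`` / ``floor((y0 - lat)/dy)``;
        points on the east/south edge of the extent are clamped inward so the
        closed extent maps onto valid cells.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ny, nx = self.shape
        col = np.floor((lon - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - lat) / self.dy).astype(int)
        inside = (col >= 0) & (lat <= self.y0) & (lon >= self.x0)
        east = lon == self.x0 + nx * self.dx
        south = lat == self.y0 - ny * self.dy
        col = np.where(east, nx - 1, col)
        row = np.where(south, ny - 1, row)
        inside &= (col < nx) & (row < ny) & (row >= 0)
        return row, col, inside

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            [self.x0, self.y0, self.dx, self.dy],
            [other.x0, other.y0, other.dx, other.dy],
        )

    def cell_areas_km2(self, radius_km: float = 6371.0) -> np.ndarray:
        """Spherical area of each cell: R^2 * dlam * (sin(phi_n) - sin(phi_s))."""
        lat_n = np.deg2rad(self.y0 - np.arange(self.shape[0]) * self.dy)
        lat_s = lat_n - np.deg2rad(self.dy)
        band = radius_km**2 * np.deg2rad(self.dx) * (np.sin(lat_n) - np.sin(lat_s))
        return np.repeat(band[:, None], self.shape[1], axis=1)


@dataclass
class CovariateStack:
    """Named, co-registered raster layers plus a boolean domain mask."""

    layers: dict[str, RasterGrid]
    domain_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty covariate stack")
        ref = self.reference
        for name, grid in self.layers.items():
            if not grid.same_grid(ref):
                raise ValueError(f"layer {name!r} is not co-registered with the stack")
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.domain_mask.shape != ref.shape:
            raise ValueError("domain mask shape mismatch")

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def complete_mask(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Domain cells with finite values in every requested layer."""
        mask = self.domain_mask.copy()
        for name in names or self.names:
            mask &= self.layers[name].mask
        return mask

    def values_at(self, rows, cols, names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(names or self.names)
        return pd.DataFrame(
            {name: self.layers[name].data[rows, cols] for name in names}
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def climate_anomaly(future: RasterGrid, baseline: RasterGrid) -> RasterGrid:
    """Cell-wise ``future - baseline``; nodata in either input propagates."""
    if not future.same_grid(baseline):
        raise ValueError("anomaly inputs are not co-registered")
    data = future.data - baseline.data
    return replace(
        future,
        data=data,
        name=f"d{baseline.name}" if baseline.name else "anomaly",
    )


def focal_fill(grid: RasterGrid, window: int = 19, stat: str = "mean") -> RasterGrid:
    """Fill nodata cells with the mean of valid cells in a centered window.

    Single pass: valid cells are never altered and freshly filled values do
    not feed later fills within the same call.  Cells whose window holds no
    valid neighbour stay nodata.
    """
    if stat != "mean":
        raise ValueError("only the mean statistic is supported")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    valid = grid.mask
    if valid.all():
        return replace(grid, data=grid.data.copy())
    filled_from = np.where(valid, grid.data, 0.0)
    # uniform_filter returns window means; multiply back to sums.  Constant
    # zero padding makes edge neighbourhoods truncate correctly.
    sums = ndimage.uniform_filter(filled_from, size=window, mode="constant") * window**2
    counts = (
        ndimage.uniform_filter(valid.astype(float), size=window, mode="constant")
        * window**2
    )
    counts = np.round(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = grid.data.copy()
    fill_cells = ~valid & (counts > 0)
    out[fill_cells] = means[fill_cells]
    return replace(grid, data=out)


def extract_at_points(
    stack: CovariateStack,
    lon: Sequence[float],
    lat: Sequence[float],
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Value of the cell containing each point, for each layer.

    Output row order equals input order.  Points outside the grid extent (or
    on nodata for a layer) carry NaN for the affected layers; the boolean
    ``in_extent`` column flags out-of-extent points.
    """
    names = list(names or stack.names)
    ref = stack.reference
    row, col, inside = ref.index_of(lon, lat)
    row_c = np.where(inside, row, 0)
    col_c = np.where(inside, col, 0)
    out = {}
    for name in names:
        vals = stack.layers[name].data[row_c, col_c]
        out[name] = np.where(inside, vals, np.nan)
    frame = pd.DataFrame(out)
    frame["in_extent"] = inside
    return frame


def sample_background(
    stack: CovariateStack,
    n: int = 100_000,
    seed: int | np.random.Generator | None = None,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Uniform random sample (without replacement) of domain pixels.

    Emulates characterizing the realized distribution of environmental
    conditions by drawing ``n`` distinct cells from the study domain and
    attaching each layer's value plus the cell-center coordinates.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(stack.domain_mask)
    if idx.size < n:
        warnings.warn(
            f"domain holds only {idx.size} cells; sampling all of them",
            stacklevel=2,
        )
        chosen = idx
    else:
        chosen = rng.choice(idx, size=n, replace=False)
    ref = stack.reference
    rows, cols = np.unravel_index(chosen, ref.shape)
    frame = stack.values_at(rows, cols, names)
    frame.insert(0, "latitude", ref.lat_centers[rows])
    frame.insert(0, "longitude", ref.lon_centers[cols])
    return frame


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grids + JSON manifest
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path) -> None:
    if not np.isclose(grid.dx, grid.dy):
        raise ValueError("ASCII grids require square cells")
    ny, nx = grid.shape
    data = np.where(grid.mask, grid.data, _NODATA)
    header = (
        f"ncols {nx}\nnrows {ny}\n"
        f"xllcorner {grid.x0!r}\nyllcorner {grid.y0 - ny * grid.dy!r}\n"
        f"cellsize {grid.dx!r}\nNODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path, name: str = "", units: str = "") -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    cell = header["cellsize"]
    return RasterGrid(
        data=data,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + header["nrows"] * cell,
        dx=cell,
        dy=cell,
        name=name or Path(path).stem,
        units=units,
    )


def write_stack(stack: CovariateStack, directory, manifest: str = "stack.json") -> Path:
    """Write each layer as an ASCII grid plus a manifest JSON and domain mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, grid in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(grid, directory / fname)
        entries[name] = {"path": fname, "units": grid.units}
    mask_grid = replace(stack.reference, data=stack.domain_mask.astype(float))
    write_ascii_grid(mask_grid, directory / "domain_mask.asc")
    manifest_path = directory / manifest
    manifest_path.write_text(
        json.dumps(
            {"layers": entries, "domain_mask": "domain_mask.asc"},
            indent=2, sort_keys=True,
        )
    )
    return manifest_path


def read_stack(manifest_path) -> CovariateStack:
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    layers = {
        name: read_ascii_grid(base / entry["path"], name, entry.get("units", ""))
        for name, entry in spec["layers"].items()
    }
    mask = read_ascii_grid(base / spec["domain_mask"]).data
    return CovariateStack(layers=layers, domain_mask=np.nan_to_num(mask) > 0.5)
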