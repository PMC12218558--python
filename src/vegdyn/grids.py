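"""Georeferenced raster containers and I/O.

A :class:`Grid` is one 2-D field with an affine georeference, an EPSG
coordinate reference, and a validity mask; a :class:`RasterStack` is a
time-ordered sequence of grids on one common geometry.  GeoTIFF is the
primary on-disk format: files are written through :mod:`tifffile` with the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and
the GDAL nodata convention, so they round-trip through any GIS.

Conventions: row 0 is the northernmost row, the transform origin is the
outer north-west corner of the grid (pixel-is-area), and all statistics
downstream operate on cell-center coordinates in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "GeoTransform",
    "Grid",
    "RasterStack",
    "read_grid",
    "write_grid",
    "align",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS = 3072


@dataclass(frozen=True)
class GeoTransform:
    """Axis-aligned affine georeference.

    ``(x0, y0)`` is the outer NW corner of cell (0, 0); ``dx`` is the cell
    width (positive eastward) and ``dy`` the cell height (negative for the
    north-up convention used throughout).
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise ValueError("pixel sizes must be nonzero")

    def cell_center(self, row, col):
        """World coordinates of the center of cell (row, col)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def world_to_index(self, x, y):
        """Fractional (row, col) of world point(s); 0.0 is a cell center."""
        col = (np.asarray(x) - self.x0) / self.dx - 0.5
        row = (np.asarray(y) - self.y0) / self.dy - 0.5
        return row, col

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer extent."""
        rows, cols = shape
        xs = sorted((self.x0, self.x0 + cols * self.dx))
        ys = sorted((self.y0, self.y0 + rows * self.dy))
        return xs[0], ys[0], xs[1], ys[1]


@dataclass
class Grid:
    """One georeferenced 2-D field.

    ``mask`` follows the :mod:`numpy.ma` convention: True marks an invalid
    (nodata) cell.  Masked cells are excluded from every downstream
    statistic.
    """

    values: np.ndarray
    transform: GeoTransform
    crs: str = "EPSG:4326"
    mask: np.ndarray | None = None
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~self.mask

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs == other.crs
        )

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        return Grid(values, self.transform, self.crs, mask, self.nodata)


@dataclass
class RasterStack:
    """Time-ordered grids on one common geometry."""

    grids: list[Grid]
    time_index: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("RasterStack needs at least one grid")
        ref = self.grids[0]
        for g in self.grids[1:]:
            if not g.same_geometry(ref):
                raise ValueError("all grids in a stack must share geometry")
        if not self.time_index:
            self.time_index = list(range(len(self.grids)))
        if len(self.time_index) != len(self.grids):
            raise ValueError("time_index length mismatch")
        if any(b <= a for a, b in zip(self.time_index, self.time_index[1:])):
            raise ValueError("time_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self) -> Iterator[Grid]:
        return iter(self.grids)

    def __getitem__(self, i: int) -> Grid:
        return self.grids[i]

    @property
    def geometry(self) -> Grid:
        return self.grids[0]

    def as_array(self) -> np.ma.MaskedArray:
        """(time, rows, cols) masked array view of the stack."""
        vals = np.stack([g.values for g in self.grids])
        mask = np.stack([g.mask for g in self.grids])
        return np.ma.MaskedArray(vals, mask=mask)


def _epsg_code(crs: str) -> int:
    crs = crs.strip().upper()
    if crs.startswith("EPSG:"):
        return int(crs.split(":")[1])
    raise ValueError(f"unsupported CRS {crs!r}; use 'EPSG:<code>'")


def _geo_key_directory(crs: str) -> tuple[int, ...]:
    code = _epsg_code(crs)
    geographic = code == 4326 or 4000 <= code < 5000
    loc_key = _KEY_GEOGRAPHIC_TYPE if geographic else _KEY_PROJECTED_CS
    model = 2 if geographic else 1
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, model),
        (_KEY_RASTER_TYPE, 0, 1, 1),  # pixel-is-area
        (loc_key, 0, 1, code),
    ]
    header = (1, 1, 0, len(keys))
    return header + tuple(v for k in keys for v in k)


def write_grid(grid: Grid, path) -> None:
    """Write a grid as a single-band float64 GeoTIFF.

    Masked cells are stored as the grid's nodata value and tagged with the
    GDAL nodata convention, so the file reads back mask-identical here and
    in standard GIS tools.
    """
    data = np.where(grid.mask, grid.nodata, grid.values).astype(np.float64)
    keys = _geo_key_directory(grid.crs)
    nodata_str = str(grid.nodata)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(grid.transform.dx), abs(grid.transform.dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.transform.x0, grid.transform.y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(keys), keys),
        (_TAG_GDAL_NODATA, "s", len(nodata_str), nodata_str),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _parse_geotiff_tags(page) -> tuple[GeoTransform, str, float | None]:
    tags = page.tags
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(
            "file carries no GeoTIFF georeference (ModelPixelScale/ModelTiepoint missing); "
            "refusing to assume an identity transform"
        )
    sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
    tie = tags[_TAG_TIEPOINT].value
    i, j, _, x, y = tie[0], tie[1], tie[2], tie[3], tie[4]
    # tie point maps raster (i, j) to world (x, y); shift back to (0, 0)
    x0 = x - i * sx
    y0 = y + j * sy
    crs = "EPSG:4326"
    if _TAG_GEO_KEYS in tags:
        keys = tags[_TAG_GEO_KEYS].value
        for k in range(4, len(keys) - 3, 4):
            key_id, _, _, val = keys[k : k + 4]
            if key_id in (_KEY_GEOGRAPHIC_TYPE, _KEY_PROJECTED_CS):
                crs = f"EPSG:{val}"
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA].value)
    return GeoTransform(x0, y0, sx, -sy), crs, nodata


def _read_netcdf(path, variable: str | None, band: int) -> Grid:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    try:
        if variable is None:
            candidates = [v for v in ds.data_vars if ds[v].ndim >= 2]
            if not candidates:
                raise ValueError(f"no 2-D variable found in {path}")
            variable = candidates[0]
        da = ds[variable]
        if da.ndim == 3:
            da = da[band - 1]
        lat = da[da.dims[-2]].values
        lon = da[da.dims[-1]].values
        dy = float(lat[1] - lat[0]) if len(lat) > 1 else -1.0
        dx = float(lon[1] - lon[0]) if len(lon) > 1 else 1.0
        vals = np.asarray(da.values, dtype=np.float64)
        if dy > 0:  # south-up on disk; flip to row 0 = north
            vals = vals[::-1]
            lat = lat[::-1]
            dy = -dy
        gt = GeoTransform(float(lon[0]) - dx / 2, float(lat[0]) - dy / 2, dx, dy)
        return Grid(vals, gt, "EPSG:4326", ~np.isfinite(vals))
    finally:
        ds.close()


def read_grid(path, band: int = 1, variable: str | None = None) -> Grid:
    """Read one band of a GeoTIFF (or a NetCDF variable) as a Grid.

    Parameters
    ----------
    band:
        1-based band index for multi-band files.
    variable:
        NetCDF variable name; ignored for GeoTIFF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".nc", ".nc4", ".cdf"}:
        return _read_netcdf(path, variable, band)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        transform, crs, nodata = _parse_geotiff_tags(page)
        series = tif.series[0]
        axes = series.axes
        data = series.asarray()
    if data.ndim == 3:
        # the non-spatial axis (samples or pages) carries the bands
        band_axis = next(i for i, a in enumerate(axes) if a not in "YX")
        n_bands = data.shape[band_axis]
        if not 1 <= band <= n_bands:
            raise IndexError(f"band {band} out of range 1..{n_bands}")
        data = np.take(data, band - 1, axis=band_axis)
    elif band != 1:
        raise IndexError(f"band {band} requested from single-band file")
    data = np.asarray(data, dtype=np.float64)
    mask = ~np.isfinite(data)
    if nodata is not None:
        mask |= data == nodata
    return Grid(data, transform, crs, mask, nodata if nodata is not None else -9999.0)


def _check_overlap(grid: Grid, reference: Grid) -> None:
    bs = grid.transform.bounds(grid.shape)
    br = reference.transform.bounds(reference.shape)
    if bs[0] >= br[2] or br[0] >= bs[2] or bs[1] >= br[3] or br[1] >= bs[3]:
        raise ValueError(
            f"grids do not overlap: source extent {bs}, reference extent {br}"
        )


def align(grid: Grid, reference: Grid, method: str = "bilinear") -> Grid:
    """Resample ``grid`` onto the geometry of ``reference``.

    ``nearest`` (mandatory for categorical fields) picks the enclosing
    source cell; ``bilinear`` interpolates from the four surrounding cell
    centers and yields a masked cell whenever any contributor is masked or
    out of the source extent — conservative, so no value is fabricated at
    nodata edges.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if grid.crs != reference.crs:
        raise ValueError(f"CRS mismatch: {grid.crs} vs {reference.crs}")
    if grid.same_geometry(reference):
        return Grid(grid.values.copy(), reference.transform, reference.crs,
                    grid.mask.copy(), grid.nodata)
    _check_overlap(grid, reference)

    rows, cols = reference.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = reference.transform.cell_center(rr, cc)
    fr, fc = grid.transform.world_to_index(x, y)
    nr, nc = grid.shape

    if method == "nearest":
        ir = np.rint(fr).astype(int)
        ic = np.rint(fc).astype(int)
        inside = (ir >= 0) & (ir < nr) & (ic >= 0) & (ic < nc)
        out = np.full((rows, cols), grid.nodata, dtype=np.float64)
        mask = np.ones((rows, cols), dtype=bool)
        irc, icc = ir[inside], ic[inside]
        out[inside] = grid.values[irc, icc]
        mask[inside] = grid.mask[irc, icc]
        return Grid(out, reference.transform, reference.crs, mask, grid.nodata)

    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    wr = fr - r0
    wc = fc - c0
    # a zero-weight neighbor may fall outside the grid without harm
    r1 = np.where(wr > 0, r0 + 1, r0)
    c1 = np.where(wc > 0, c0 + 1, c0)
    inside = (r0 >= 0) & (r1 < nr) & (c0 >= 0) & (c1 < nc)
    r0c, r1c = np.clip(r0, 0, nr - 1), np.clip(r1, 0, nr - 1)
    c0c, c1c = np.clip(c0, 0, nc - 1), np.clip(c1, 0, nc - 1)
    v00 = grid.values[r0c, c0c]
    v01 = grid.values[r0c, c1c]
    v10 = grid.values[r1c, c0c]
    v11 = grid.values[r1c, c1c]
    any_masked = (
        grid.mask[r0c, c0c] | grid.mask[r0c, c1c]
        | grid.mask[r1c, c0c] | grid.mask[r1c, c1c]
    )
    out = (
        v00 * (1 - wr) * (1 - wc)
        + v01 * (1 - wr) * wc
        + v10 * wr * (1 - wc)
        + v11 * wr * wc
    )
    mask = ~inside | any_masked
    out = np.where(mask, grid.nodata, out)
    return Grid(out, reference.transform, reference.crs, mask, grid.nodata)
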