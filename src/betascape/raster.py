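"""Georeferenced raster grids and point extraction.

A :class:`RasterGrid` is a single-band, north-up grid in geographic
coordinates with an explicit affine transform and a nodata sentinel.
Pixel (0, 0) sits at the grid's northwest corner and pixel intervals are
half-open ``[edge, edge + size)`` along each axis, so every point inside
the extent maps to exactly one pixel.

Extraction at site locations follows the field practice for patchy
remote-sensing products: read the pixel under the point, and if it is
nodata, progressively coarsen the grid by nearest-neighbour resampling
(integer factors 2, 3, ...) until a valid value appears or the maximum
factor is exhausted, recording the factor used as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RasterGrid",
    "ExtractionResult",
    "extract_at_points",
    "classify_points",
    "median_composite",
    "coarsen",
    "latlon_grids",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
]

# GeoTIFF tag ids used for the minimal georeferencing we read/write.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """Single-band north-up raster.

    Parameters
    ----------
    values
        2-D array (rows x cols); integer arrays hold categorical labels.
    transform
        Six-term affine ``(a, b, c, d, e, f)`` mapping pixel (col, row) to
        geographic (x, y): ``x = c + a*col``, ``y = f + e*row`` with
        ``b = d = 0``, ``a > 0`` (west-to-east) and ``e < 0`` (north-down).
    nodata
        Sentinel marking missing pixels, or None if the grid is complete.
    crs_tag
        Free-text CRS label; defaults to geographic WGS84.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    nodata: float | int | None = None
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be a 2-D array")
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0:
            raise ValueError("only north-up (non-rotated) transforms are supported")
        if a <= 0 or e >= 0:
            raise ValueError("transform must have a > 0 and e < 0 (north-up)")

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer edges."""
        a, _, c, _, e, f = self.transform
        rows, cols = self.shape
        return (c, f + e * rows, c + a * cols, f)

    def rowcol(self, lon, lat):
        """Map geographic points to (row, col) under the half-open rule."""
        a, _, c, _, e, f = self.transform
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - c) / a).astype(int)
        row = np.floor((lat - f) / e).astype(int)
        return row, col

    def cell_center(self, row, col):
        """Geographic (lon, lat) of pixel centers."""
        a, _, c, _, e, f = self.transform
        row = np.asarray(row)
        col = np.asarray(col)
        return c + a * (col + 0.5), f + e * (row + 0.5)

    def contains(self, lon, lat):
        west, south, east, north = self.extent
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= west) & (lon < east) & (lat > south) & (lat <= north)

    def valid_mask(self) -> np.ndarray:
        """True where the pixel carries data."""
        mask = np.isfinite(self.values.astype(float))
        if self.nodata is not None:
            if isinstance(self.nodata, float) and np.isnan(self.nodata):
                pass  # already covered by the finite check
            else:
                mask &= self.values != self.nodata
        return mask

    def copy_with(self, **kwargs) -> "RasterGrid":
        return replace(self, **kwargs)


@dataclass
class ExtractionResult:
    """Values extracted at points plus fallback provenance.

    ``factor[i]`` is the coarsening factor at which point *i* found data
    (1 = direct hit); ``missing[i]`` is True when the fallback was
    exhausted without finding a valid pixel — never silently filled.
    """

    values: np.ndarray
    factor: np.ndarray
    missing: np.ndarray


def coarsen(grid: RasterGrid, factor: int) -> RasterGrid:
    """Nearest-neighbour coarsening by an integer factor.

    Each factor-``k`` pixel takes the value of the *valid* constituent
    fine pixel nearest to the coarse-pixel center (row-major tie-break);
    it is nodata only when every fine pixel in the block is nodata.  The
    output value set is therefore always a subset of the input's.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return grid
    rows, cols = grid.shape
    out_rows = -(-rows // factor)
    out_cols = -(-cols // factor)
    vals = grid.values
    valid = grid.valid_mask()
    nodata = grid.nodata if grid.nodata is not None else np.nan
    out = np.full((out_rows, out_cols), nodata, dtype=float)
    # center of the coarse pixel in fine-pixel index space
    ctr = (factor - 1) / 2.0
    for R in range(out_rows):
        r0, r1 = R * factor, min((R + 1) * factor, rows)
        for C in range(out_cols):
            c0, c1 = C * factor, min((C + 1) * factor, cols)
            block_valid = valid[r0:r1, c0:c1]
            if not block_valid.any():
                continue
            rr, cc = np.nonzero(block_valid)
            d2 = (rr - ctr) ** 2 + (cc - ctr) ** 2
            k = int(np.argmin(d2))  # argmin is row-major-first on ties
            out[R, C] = vals[r0 + rr[k], c0 + cc[k]]
    a, b, c, d, e, f = grid.transform
    new_transform = (a * factor, b, c, d, e * factor, f)
    if np.issubdtype(vals.dtype, np.integer) and grid.nodata is not None:
        out = out.astype(vals.dtype)
    return RasterGrid(out, new_transform, nodata=grid.nodata, crs_tag=grid.crs_tag)


def extract_at_points(
    grid: RasterGrid, lons, lats, max_fallback_factor: int = 8
) -> ExtractionResult:
    """Extract raster values at points with progressive-coarsening fallback.

    Raises if any point lies outside the grid extent.  Points that remain
    on nodata at every factor up to ``max_fallback_factor`` come back with
    ``missing=True`` and a NaN value.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    inside = grid.contains(lons, lats)
    if not inside.all():
        bad = np.nonzero(~inside)[0]
        raise ValueError(
            f"{bad.size} point(s) outside raster extent, first at index {bad[0]}: "
            f"({lons[bad[0]]}, {lats[bad[0]]})"
        )
    n = lons.size
    values = np.full(n, np.nan)
    factor = np.zeros(n, dtype=int)
    missing = np.ones(n, dtype=bool)
    pending = np.arange(n)
    g = grid
    for k in range(1, max_fallback_factor + 1):
        if pending.size == 0:
            break
        if k > 1:
            g = coarsen(grid, k)
        row, col = g.rowcol(lons[pending], lats[pending])
        rows, cols = g.shape
        row = np.clip(row, 0, rows - 1)
        col = np.clip(col, 0, cols - 1)
        vals = g.values[row, col].astype(float)
        ok = g.valid_mask()[row, col]
        hit = pending[ok]
        values[hit] = vals[ok]
        factor[hit] = k
        missing[hit] = False
        pending = pending[~ok]
    return ExtractionResult(values=values, factor=factor, missing=missing)


def classify_points(class_grid: RasterGrid, lons, lats) -> ExtractionResult:
    """Label points by the class of their containing pixel (no fallback)."""
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    inside = class_grid.contains(lons, lats)
    if not inside.all():
        raise ValueError("point(s) outside class grid extent")
    row, col = class_grid.rowcol(lons, lats)
    vals = class_grid.values[row, col]
    ok = class_grid.valid_mask()[row, col]
    return ExtractionResult(
        values=np.where(ok, vals, -1), factor=np.ones(lons.size, dtype=int), missing=~ok
    )


def median_composite(grids: list[RasterGrid]) -> RasterGrid:
    """Per-pixel median across years, ignoring nodata.

    A pixel is nodata in the composite only when it is nodata in every
    input.  An even count of valid values yields the mean of the two
    central ones.
    """
    if not grids:
        raise ValueError("median_composite requires at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or not np.allclose(g.transform, ref.transform):
            raise ValueError("all grids must share shape and transform")
    stack = np.stack([np.where(g.valid_mask(), g.values.astype(float), np.nan) for g in grids])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels stay nodata
        med = np.nanmedian(stack, axis=0)
    nodata = ref.nodata if ref.nodata is not None else np.nan
    out = np.where(np.isnan(med), nodata, med)
    return RasterGrid(out, ref.transform, nodata=ref.nodata, crs_tag=ref.crs_tag)


def latlon_grids(grid: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Synthesize latitude and longitude rasters from a grid's geometry."""
    rows, cols = grid.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    lon, lat = grid.cell_center(rr, cc)
    return (
        RasterGrid(lat, grid.transform, crs_tag=grid.crs_tag),
        RasterGrid(lon, grid.transform, crs_tag=grid.crs_tag),
    )


# -- I/O ---------------------------------------------------------------


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (requires square pixels)."""
    a, _, c, _, e, f = grid.transform
    if not np.isclose(a, -e):
        raise ValueError("ASCII grid format requires square pixels")
    rows, cols = grid.shape
    nodata = grid.nodata if grid.nodata is not None else -9999
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner {c!r}\nyllcorner {f + e * rows!r}\n"
        f"cellsize {a!r}\nNODATA_value {nodata!r}\n"
    )
    vals = grid.values
    if grid.nodata is None:
        vals = np.where(np.isfinite(vals.astype(float)), vals, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, dtype=float) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, dtype=dtype)
    cols = int(header["ncols"])
    rows = int(header["nrows"])
    size = header["cellsize"]
    vals = vals.reshape(rows, cols)
    transform = (size, 0.0, header["xllcorner"], 0.0, -size, header["yllcorner"] + size * rows)
    nodata = header.get("nodata_value")
    if dtype is int or np.issubdtype(np.dtype(dtype), np.integer):
        nodata = int(nodata) if nodata is not None else None
    return RasterGrid(vals, transform, nodata=nodata)


def write_geotiff(grid_or_rgb, path, transform=None, nodata=None) -> None:
    """Write a single-band RasterGrid, or an (rows, cols, 3) RGB array, as GeoTIFF.

    Georeferencing is carried by the ModelPixelScale and ModelTiepoint
    tags plus GDAL's nodata convention — enough for GIS tools to place
    the grid, without a full CRS key directory.
    """
    import tifffile

    if isinstance(grid_or_rgb, RasterGrid):
        data = grid_or_rgb.values
        transform = grid_or_rgb.transform
        nodata = grid_or_rgb.nodata
    else:
        data = np.asarray(grid_or_rgb)
        if transform is None:
            raise ValueError("transform required when writing a bare array")
    a, _, c, _, e, f = transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (a, -e, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    photometric = "rgb" if data.ndim == 3 else "minisblack"
    tifffile.imwrite(path, data, photometric=photometric, extratags=extratags)


def read_geotiff(path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tie = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is None or tie is None:
        raise ValueError(f"{path} lacks georeferencing tags")
    transform = (scale[0], 0.0, tie[3], 0.0, -scale[1], tie[4])
    nodata = tags.get(_TAG_GDAL_NODATA)
    if nodata is not None:
        nodata = float(nodata)
        if np.issubdtype(data.dtype, np.integer):
            nodata = int(nodata)
    return RasterGrid(data, transform, nodata=nodata)
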