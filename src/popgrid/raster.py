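"""Grid rasters: the in-memory carrier for covariates and population surfaces.

A :class:`GridRaster` is a 2-D value array plus georeferencing in a projected
coordinate system with meter units: the coordinates of the outer (north-west)
corner of pixel ``(0, 0)``, a square pixel size, a CRS identifier and a nodata
sentinel.  Row 0 is the northernmost row, indices are 0-based, and extents are
half-open intervals ``[origin_x, origin_x + ncols * pixel_size)``.

Persistence uses the ESRI ASCII grid format (plain text, single band) with a
JSON sidecar (``<path>.aux.json``) carrying the CRS identifier and the stored
dtype, so integer zone rasters round-trip exactly and float rasters round-trip
to full double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage


class RasterError(Exception):
    """Base class for raster contract violations."""


class UnsupportedRasterError(RasterError):
    """File is not a supported single-band, square-pixel raster."""


class EmptyIntersectionError(RasterError):
    """Rasters to be aligned have no common extent."""


class CRSMismatchError(RasterError):
    """Operands do not share a coordinate reference system."""


DEFAULT_NODATA = -9999.0


@dataclass
class GridRaster:
    """Single-band raster on a square-pixel projected grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; cells equal to ``nodata`` are missing.
    origin_x, origin_y : float
        Projected coordinates (meters) of the outer corner of pixel (0, 0),
        i.e. the west edge / north edge of the grid.
    pixel_size : float
        Square pixel edge length in meters; must be positive.
    crs_id : str
        Text identifier of the projected CRS (e.g. ``"local-aea"``).
    nodata : float
        Sentinel for missing cells (compared exactly).
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    crs_id: str = "local"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise RasterError(f"values must be 2-D, got ndim={self.values.ndim}")
        if not self.pixel_size > 0:
            raise RasterError(f"pixel_size must be > 0, got {self.pixel_size}")
        finite = np.isfinite(self.values)
        if not bool(np.all(finite | (self.values == self.nodata))):
            raise RasterError("every cell must be finite or equal the nodata sentinel")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.pixel_size,
            self.origin_x + self.ncols * self.pixel_size,
            self.origin_y,
        )

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of pixel-center coordinates, shape (nrows, ncols)."""
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(self.nrows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    @property
    def data_mask(self) -> np.ndarray:
        """Boolean mask, True where the cell holds data (not nodata)."""
        return self.values != self.nodata

    def like(self, values: np.ndarray, nodata: float | None = None) -> "GridRaster":
        """New raster sharing this grid's georeferencing."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise RasterError(f"shape mismatch: {values.shape} vs {self.shape}")
        return GridRaster(
            values=values,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            pixel_size=self.pixel_size,
            crs_id=self.crs_id,
            nodata=self.nodata if nodata is None else nodata,
        )

    def same_grid(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and self.crs_id == other.crs_id
            and np.isclose(self.origin_x, other.origin_x, rtol=0, atol=1e-6)
            and np.isclose(self.origin_y, other.origin_y, rtol=0, atol=1e-6)
            and np.isclose(self.pixel_size, other.pixel_size, rtol=0, atol=1e-9)
        )

    def copy(self) -> "GridRaster":
        return replace(self, values=self.values.copy())


@dataclass
class ZoneRaster(GridRaster):
    """GridRaster whose values are integer unit ids (>= 1); 0 is nodata."""

    nodata: float = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise RasterError("zone raster values must be integers")
        super().__post_init__()
        data = self.values[self.values != int(self.nodata)]
        if data.size and data.min() < 1:
            raise RasterError("zone ids must be >= 1")

    def zone_ids(self) -> np.ndarray:
        """Sorted unique unit ids present in the raster."""
        ids = np.unique(self.values)
        return ids[ids != int(self.nodata)]


# -- I/O -------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_raster(path: str | Path, raster: GridRaster) -> Path:
    """Write a raster as an ESRI ASCII grid plus a JSON sidecar.

    Integer arrays are written as integers (exact round-trip); floats are
    written with 17 significant digits (double-precision round-trip).
    """
    path = Path(path)
    vals = raster.values
    is_int = np.issubdtype(vals.dtype, np.integer)
    fmt = "%d" if is_int else "%.17g"
    xmin, ymin, _, _ = raster.bounds
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {xmin!r}\n"
        f"yllcorner {ymin!r}\n"
        f"cellsize {raster.pixel_size!r}\n"
        f"NODATA_value {int(raster.nodata) if is_int else raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    sidecar = {"crs_id": raster.crs_id, "dtype": str(vals.dtype),
               "zone_raster": isinstance(raster, ZoneRaster)}
    Path(str(path) + ".aux.json").write_text(json.dumps(sidecar))
    return path


def read_raster(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    Raises
    ------
    UnsupportedRasterError
        For non-square pixels (``dx``/``dy`` headers) or non-ASCII-grid files.
    IOError
        If the file does not exist or cannot be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                key = parts[0].lower()
                if key in ("dx", "dy"):
                    raise UnsupportedRasterError(
                        f"{path}: non-square pixels (dx/dy headers) are not supported"
                    )
                if key not in _HEADER_KEYS:
                    raise UnsupportedRasterError(f"{path}: unknown header key {parts[0]!r}")
                header[key] = float(parts[1])
            else:
                break
    missing = [k for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize") if k not in header]
    if missing:
        raise UnsupportedRasterError(f"{path}: not an ASCII grid (missing header {missing})")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(path, skiprows=len(header))
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise UnsupportedRasterError(
            f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    crs_id = "local"
    sidecar_path = Path(str(path) + ".aux.json")
    as_zone = False
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        crs_id = sidecar.get("crs_id", crs_id)
        dtype = sidecar.get("dtype")
        if dtype is not None:
            values = values.astype(dtype)
        as_zone = bool(sidecar.get("zone_raster", False))
    cls = ZoneRaster if as_zone else GridRaster
    return cls(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * header["cellsize"],
        pixel_size=header["cellsize"],
        crs_id=crs_id,
        nodata=int(nodata) if as_zone else nodata,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# -- alignment -------------------------------------------------------------

def align_stack(
    rasters: Sequence[GridRaster],
    categorical: Sequence[bool] | None = None,
) -> list[GridRaster]:
    """Resample rasters onto the common intersection extent at the finest pixel size.

    Categorical layers (``categorical[i]`` True) use nearest-neighbor
    resampling; continuous layers use bilinear interpolation with nodata
    propagated conservatively (any nodata among the four neighbors yields
    nodata).  Rasters already on the target grid are returned unchanged.
    """
    rasters = list(rasters)
    if not rasters:
        return []
    if categorical is None:
        categorical = [False] * len(rasters)
    if len(categorical) != len(rasters):
        raise ValueError("categorical flags must match rasters in length")
    crs = rasters[0].crs_id
    for r in rasters:
        if r.crs_id != crs:
            raise CRSMismatchError(f"CRS mismatch: {r.crs_id!r} != {crs!r}")

    xmin = max(r.bounds[0] for r in rasters)
    ymin = max(r.bounds[1] for r in rasters)
    xmax = min(r.bounds[2] for r in rasters)
    ymax = min(r.bounds[3] for r in rasters)
    if xmin >= xmax or ymin >= ymax:
        raise EmptyIntersectionError("rasters have no overlapping extent")
    ps = min(r.pixel_size for r in rasters)
    ncols = int(np.floor((xmax - xmin) / ps + 1e-9))
    nrows = int(np.floor((ymax - ymin) / ps + 1e-9))
    if ncols < 1 or nrows < 1:
        raise EmptyIntersectionError("intersection extent smaller than one pixel")
    template = GridRaster(
        values=np.zeros((nrows, ncols)),
        origin_x=xmin, origin_y=ymax, pixel_size=ps, crs_id=crs,
    )

    out = []
    for r, is_cat in zip(rasters, categorical):
        if r.same_grid(template):
            out.append(r.copy())
            continue
        out.append(_resample_to(r, template, nearest=is_cat))
    return out


def _resample_to(src: GridRaster, template: GridRaster, nearest: bool) -> GridRaster:
    X, Y = template.center_coords()
    col_f = (X - src.origin_x) / src.pixel_size - 0.5
    row_f = (src.origin_y - Y) / src.pixel_size - 0.5
    if nearest:
        rows = np.clip(np.rint(row_f).astype(int), 0, src.nrows - 1)
        cols = np.clip(np.rint(col_f).astype(int), 0, src.ncols - 1)
        vals = src.values[rows, cols]
    else:
        work = np.where(src.data_mask, src.values.astype(float), np.nan)
        vals = ndimage.map_coordinates(
            work, [row_f, col_f], order=1, mode="nearest"
        )
        vals = np.where(np.isfinite(vals), vals, src.nodata)
    return GridRaster(
        values=vals,
        origin_x=template.origin_x,
        origin_y=template.origin_y,
        pixel_size=template.pixel_size,
        crs_id=src.crs_id,
        nodata=src.nodata,
    )
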