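"""Dasymetric redistribution: census counts to pixels, mass conserved.

Each zone's harmonized count is spread over its pixels proportionally to the
weighting layer, so that the pixel sum of every zone equals its census count
exactly (up to float rounding) — the central invariant of the whole pipeline.
Weights are relative: scaling the weighting layer by any positive constant
leaves the result unchanged.

Products follow the people-per-pixel (ppp) and people-per-hectare (pph)
conventions; on a 100 m grid one pixel is one hectare and the two coincide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .harmonize import HarmonizedCensus
from .raster import GridRaster, write_raster
from .zones import ZoneRaster

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8


class DasymetricError(Exception):
    pass


@dataclass
class PopulationRaster:
    """People-per-pixel surface with its year label."""

    ppp: GridRaster
    year: str = ""
    undistributed: float = 0.0

    def pph(self) -> GridRaster:
        return ppp_to_pph(self)

    def total(self) -> float:
        return float(self.ppp.values[self.ppp.data_mask].sum())


def redistribute(
    census: HarmonizedCensus,
    weights: GridRaster,
    zones: ZoneRaster,
) -> PopulationRaster:
    """Allocate each zone's count over its pixels proportionally to the weights.

    ``ppp(pixel) = count(zone) * w(pixel) / sum(w over usable pixels of zone)``.

    Pixels whose weight is nodata receive zero people (their covariates were
    unknown, so their share moves to the zone's usable pixels).  A zone whose
    usable weights sum to zero — including one with no usable pixel at all —
    falls back to uniform allocation over all its pixels, with a warning, so
    census mass is never lost.  Pixels outside every zone are nodata.  Census
    zones absent from the raster are logged and their counts reported as
    ``undistributed``.
    """
    if not weights.same_grid(zones):
        raise DasymetricError("weights and zones must share the grid")
    zvals = zones.values
    in_zone = zones.data_mask
    w = np.where(weights.data_mask & in_zone, weights.values.astype(float), 0.0)
    if np.any(w < 0):
        raise DasymetricError("weights must be non-negative where defined")

    ids = zones.zone_ids()
    id_to_idx = {int(z): i for i, z in enumerate(ids)}
    idx = np.full(zvals.shape, -1, dtype=int)
    for z, i in id_to_idx.items():
        idx[zvals == z] = i

    flat_idx = idx[in_zone]
    wsum = np.bincount(flat_idx, weights=w[in_zone], minlength=len(ids))
    npix = np.bincount(flat_idx, minlength=len(ids))

    factor = np.zeros(len(ids))
    uniform = np.zeros(len(ids))
    undistributed = 0.0
    missing_in_raster = [z for z in census.counts if int(z) not in id_to_idx]
    for z in missing_in_raster:
        if census.counts[z] > 0:
            logger.warning("zone %s in census but not in raster; count %s undistributed",
                           z, census.counts[z])
            undistributed += census.counts[z]
    for z, i in id_to_idx.items():
        count = census.counts.get(z)
        if count is None:
            raise DasymetricError(f"zone {z} present in raster but missing from census")
        if wsum[i] > 0:
            factor[i] = count / wsum[i]
        else:
            if count > 0:
                logger.warning("zone %s: zero usable weight; uniform fallback", z)
            uniform[i] = count / npix[i]

    out = np.full(zvals.shape, weights.nodata, dtype=float)
    vals = w[in_zone] * factor[flat_idx] + uniform[flat_idx]
    out[in_zone] = vals
    ppp = GridRaster(
        values=out,
        origin_x=zones.origin_x,
        origin_y=zones.origin_y,
        pixel_size=zones.pixel_size,
        crs_id=zones.crs_id,
        nodata=weights.nodata,
    )
    return PopulationRaster(ppp=ppp, year=census.year, undistributed=undistributed)


def conservation_residuals(pop: PopulationRaster, zones: ZoneRaster,
                           census: HarmonizedCensus) -> dict[int, float]:
    """Per-zone relative residual |pixel sum - count| / max(count, 1)."""
    zvals = zones.values
    res = {}
    for z in zones.zone_ids():
        z = int(z)
        s = float(pop.ppp.values[(zvals == z)].sum())
        c = census.counts.get(z, 0.0)
        res[z] = abs(s - c) / max(c, 1.0)
    return res


def ppp_to_pph(pop: PopulationRaster) -> GridRaster:
    """People per hectare: ppp divided by the pixel area in hectares."""
    ppp = pop.ppp
    area_ha = ppp.pixel_size**2 / 10_000.0
    vals = np.where(ppp.data_mask, ppp.values / area_ha, ppp.nodata)
    return ppp.like(vals)


def export_products(
    pop: PopulationRaster,
    out_crs: str,
    out_dir: str | Path,
    iso: str = "SYN",
    ref_lonlat: tuple[float, float] = (110.0, 35.0),
) -> dict:
    """Write the ppp and pph products, reprojected to ``out_crs`` if it differs.

    When ``out_crs`` equals the working CRS the grids are written as-is (the
    mass-true reference product).  Otherwise a geographic export is produced
    via a local tangent-plane (equirectangular) mapping around ``ref_lonlat``
    with nearest-neighbor sampling; reprojection can drift total mass
    slightly, so the run report records both totals and the projected-grid
    product remains the mass-true reference.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    year = pop.year or "0000"
    ppp, pph = pop.ppp, pop.pph()
    if out_crs != ppp.crs_id:
        ppp = _to_geographic(ppp, out_crs, ref_lonlat, mode="mass")
        pph = _to_geographic(pph, out_crs, ref_lonlat, mode="sample")
    paths = {
        "ppp": write_raster(out_dir / f"{iso}_ppp_{year}.asc", ppp),
        "pph": write_raster(out_dir / f"{iso}_pph_{year}.asc", pph),
    }
    exported_total = float(ppp.values[ppp.data_mask].sum())
    report = {
        "year": year,
        "out_crs": out_crs,
        "working_total": pop.total(),
        "exported_total": exported_total,
        "paths": {k: str(v) for k, v in paths.items()},
    }
    return report


def _to_geographic(raster: GridRaster, out_crs: str,
                   ref_lonlat: tuple[float, float],
                   mode: str = "sample") -> GridRaster:
    """Reproject the local meter grid to a lon/lat grid, square in degrees.

    The angular step is ``sqrt(dlon * dlat)`` — the geometric mean of the
    source pixel's angular extents — so the target pixel count roughly equals
    the source's.  ``mode='sample'`` takes the nearest source value at each
    target center (for intensities such as pph); ``mode='mass'`` instead
    drops every source pixel's value into the target cell containing its
    center, which conserves the grand total exactly (for ppp).
    """
    lon0, lat0 = ref_lonlat
    coslat = math.cos(math.radians(lat0))
    m_per_deg_lat = math.pi / 180.0 * EARTH_RADIUS_M
    m_per_deg_lon = m_per_deg_lat * coslat

    dlat = raster.pixel_size / m_per_deg_lat
    dlon = raster.pixel_size / m_per_deg_lon
    step = math.sqrt(dlat * dlon)
    xmin, ymin, xmax, ymax = raster.bounds
    lon_min = lon0 + xmin / m_per_deg_lon
    lon_max = lon0 + xmax / m_per_deg_lon
    lat_min = lat0 + ymin / m_per_deg_lat
    lat_max = lat0 + ymax / m_per_deg_lat
    ncols_out = max(1, int(math.ceil((lon_max - lon_min) / step - 1e-9)))
    nrows_out = max(1, int(math.ceil((lat_max - lat_min) / step - 1e-9)))

    if mode == "mass":
        # forward binning of source pixel centers
        X, Y = raster.center_coords()
        lon_src = lon0 + X / m_per_deg_lon
        lat_src = lat0 + Y / m_per_deg_lat
        cols = np.clip(((lon_src - lon_min) / step).astype(int), 0, ncols_out - 1)
        rows = np.clip(((lat_max - lat_src) / step).astype(int), 0, nrows_out - 1)
        vals = np.zeros((nrows_out, ncols_out))
        touched = np.zeros((nrows_out, ncols_out), dtype=bool)
        data = raster.data_mask
        np.add.at(vals, (rows[data], cols[data]), raster.values[data])
        touched[rows[data], cols[data]] = True
        vals = np.where(touched, vals, raster.nodata)
    else:
        lons = lon_min + (np.arange(ncols_out) + 0.5) * step
        lats = lat_max - (np.arange(nrows_out) + 0.5) * step
        LON, LAT = np.meshgrid(lons, lats)
        x = (LON - lon0) * m_per_deg_lon
        y = (LAT - lat0) * m_per_deg_lat
        cols = np.clip(
            np.floor((x - raster.origin_x) / raster.pixel_size).astype(int),
            0, raster.ncols - 1,
        )
        rows = np.clip(
            np.floor((raster.origin_y - y) / raster.pixel_size).astype(int),
            0, raster.nrows - 1,
        )
        vals = raster.values[rows, cols]
    return GridRaster(
        values=vals.astype(np.float32).astype(float),
        origin_x=lon_min,
        origin_y=lat_max,
        pixel_size=step,
        crs_id=out_crs,
        nodata=raster.nodata,
    )
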