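"""Self-contained synthetic study region for the full mapping pipeline.

The generator emulates the statistical structure the density model assumes,
without any real census or satellite data: smooth terrain, a few rivers,
built-up extents that grow monotonically over the census years, nighttime
lights that brighten with nearby built area, and a per-pixel ground-truth
population surface whose log density is a smooth decreasing function of the
signed distance to the built edge plus a lights term and Gaussian noise.

Two regimes realize the two hypotheses about the density/distance law:

* ``static`` — one distance-decay coefficient for all years (the law does not
  change over time, so a pooled model would be adequate);
* ``timevary`` — the decay coefficient differs by year (rapid-urbanization
  case), which is the regime where fitting each year independently pays off.

Census tessellations come in two nested granularities: coarse zones play the
role of the model's administrative units, fine zones (each wholly inside one
coarse zone) the role of the finer validation units.  Census counts are exact
zonal sums of the true surface, so conservation can be checked to float
precision end-to-end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, box
from shapely.ops import unary_union, voronoi_diagram
from sklearn.cluster import KMeans

from .covariates import distance_to_features, signed_distance_to_edge, slope_from_elevation
from .harmonize import CensusUnit
from .raster import GridRaster, ZoneRaster, write_raster
from .zones import PolygonSet, ZoneUnit, rasterize_zones, write_geojson

logger = logging.getLogger(__name__)


class SynthWorldError(Exception):
    pass


@dataclass
class WorldConfig:
    """Knobs of the synthetic study region.

    Defaults describe a 20 km x 20 km region at 100 m resolution over three
    census years, with 100 model (coarse) zones and 400 validation (fine)
    zones — sized so the full pipeline runs in minutes on one CPU.
    """

    rows: int = 200
    cols: int = 200
    pixel_size: float = 100.0           # m
    years: tuple[str, ...] = ("1990", "2000", "2010")
    n_coarse_zones: int = 100
    n_fine_zones: int = 400
    n_built_seeds: int = 12
    built_init_radius_m: float = 400.0   # blob radius in the first year
    built_growth_m: float = 300.0        # radial growth per census interval
    n_rivers: int = 2
    # density law: log density = base - decay * (signed built dist, km)
    #                              + lights_coef * (lights / lights_max) + eps
    log_base_density: float = 3.0        # ln people-per-pixel at the built edge
    dist_decay_per_km: float = 1.5       # 'static' regime decay coefficient
    timevary_decays: tuple[float, ...] = (2.4, 1.5, 0.8)
    lights_coef: float = 0.8
    noise_sigma: float = 0.2             # Gaussian sd on the log scale
    lights_max: float = 63.0             # DMSP-like digital-number ceiling
    lights_noise: float = 1.5
    lights_radius_px: int = 11           # window for built-fraction brightness
    regime: str = "static"               # 'static' | 'timevary'
    crs_id: str = "local-aea"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fine_zones < self.n_coarse_zones:
            raise SynthWorldError("n_fine_zones must be >= n_coarse_zones")
        if len(self.years) < 1:
            raise SynthWorldError("need at least one year")
        if self.regime not in ("static", "timevary"):
            raise SynthWorldError(f"unknown regime {self.regime!r}")
        for name in ("rows", "cols", "pixel_size", "n_built_seeds",
                     "built_init_radius_m", "built_growth_m", "noise_sigma",
                     "lights_max"):
            if getattr(self, name) <= 0:
                raise SynthWorldError(f"{name} must be positive")

    def decay_for_year(self, t: int) -> float:
        if self.regime == "static":
            return self.dist_decay_per_km
        return self.timevary_decays[t % len(self.timevary_decays)]


@dataclass
class SyntheticWorld:
    cfg: WorldConfig
    elevation: GridRaster
    rivers: GridRaster
    built: dict[str, GridRaster]
    lights: dict[str, GridRaster]
    true_ppp: dict[str, GridRaster]
    coarse_polys: PolygonSet
    fine_polys: PolygonSet
    coarse_zones: ZoneRaster
    fine_zones: ZoneRaster
    fine_to_coarse: dict[int, int]
    coarse_census: pd.DataFrame  # unit_id, population, year
    fine_census: pd.DataFrame

    def census_counts(self, year: str, level: str = "coarse") -> dict[int, float]:
        df = self.coarse_census if level == "coarse" else self.fine_census
        sel = df[df["year"] == year]
        return dict(zip(sel["unit_id"].astype(int), sel["population"].astype(float)))

    def census_units(self, year: str, level: str = "coarse") -> list[CensusUnit]:
        polys = self.coarse_polys if level == "coarse" else self.fine_polys
        counts = self.census_counts(year, level)
        return [CensusUnit(u.unit_id, u.polygon, counts[u.unit_id], year) for u in polys]

    def static_layers(self) -> dict[str, GridRaster]:
        return {
            "elevation": self.elevation,
            "slope": slope_from_elevation(self.elevation),
            "dist_water": distance_to_features(self.rivers),
        }


def _template(cfg: WorldConfig) -> GridRaster:
    return GridRaster(
        values=np.zeros((cfg.rows, cfg.cols)),
        origin_x=0.0,
        origin_y=cfg.rows * cfg.pixel_size,
        pixel_size=cfg.pixel_size,
        crs_id=cfg.crs_id,
    )


def _make_rivers(cfg: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """Monotone random-walk polylines crossing the grid west to east."""
    mask = np.zeros((cfg.rows, cfg.cols), dtype=bool)
    for _ in range(cfg.n_rivers):
        r = float(rng.integers(cfg.rows // 5, 4 * cfg.rows // 5))
        drift = rng.normal(0, 0.8, cfg.cols)
        drift = ndimage.gaussian_filter1d(drift, sigma=5)
        for c in range(cfg.cols):
            r = float(np.clip(r + drift[c], 0, cfg.rows - 1))
            mask[int(r), c] = True
    return mask


def _tessellate(
    cfg: WorldConfig, template: GridRaster, rng: np.random.Generator
) -> tuple[PolygonSet, PolygonSet, dict[int, int]]:
    """Irregular nested zones: k-means centers polygonized by Voronoi.

    Fine cells are the Voronoi cells of k-means cluster centers of (a sample
    of) pixel centers; coarse zones are unions of fine cells grouped by a
    second k-means on the fine centers, so nesting is exact by construction.
    """
    X, Y = template.center_coords()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    n_sample = min(10_000, pts.shape[0])
    sample = pts[rng.choice(pts.shape[0], n_sample, replace=False)]
    km_fine = KMeans(
        n_clusters=cfg.n_fine_zones, n_init=1,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(sample)
    centers = km_fine.cluster_centers_

    extent = box(*template.bounds)
    cells = voronoi_diagram(MultiPoint(centers), envelope=extent)
    fine_units: list[ZoneUnit | None] = [None] * len(centers)
    for cell in cells.geoms:
        clipped = cell.intersection(extent)
        if clipped.is_empty:
            continue
        hit = shapely.contains_xy(cell, centers[:, 0], centers[:, 1])
        (idx,) = np.nonzero(hit)
        if idx.size != 1:  # degenerate Voronoi cell; take the nearest center
            d = np.hypot(centers[:, 0] - clipped.centroid.x,
                         centers[:, 1] - clipped.centroid.y)
            idx = np.array([int(np.argmin(d))])
        fine_units[int(idx[0])] = ZoneUnit(int(idx[0]) + 1, clipped)
    fine_units = [u for u in fine_units if u is not None]
    fine = PolygonSet(fine_units, crs_id=cfg.crs_id)

    fine_centers = np.array([[u.polygon.centroid.x, u.polygon.centroid.y] for u in fine])
    km_coarse = KMeans(
        n_clusters=cfg.n_coarse_zones, n_init=1,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(fine_centers)
    fine_to_coarse = {
        u.unit_id: int(lbl) + 1 for u, lbl in zip(fine, km_coarse.labels_)
    }
    coarse_units = []
    for cid in range(1, cfg.n_coarse_zones + 1):
        members = [u.polygon for u in fine if fine_to_coarse[u.unit_id] == cid]
        if not members:
            continue
        coarse_units.append(ZoneUnit(cid, unary_union(members)))
    coarse = PolygonSet(coarse_units, crs_id=cfg.crs_id)
    return coarse, fine, fine_to_coarse


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Deterministically generate the full synthetic study region.

    The same config (including seed) always yields a bit-identical world.
    """
    rng = np.random.default_rng(cfg.seed)
    template = _template(cfg)
    ps = cfg.pixel_size

    # terrain: smoothed Gaussian field scaled to 0..500 m
    rough = rng.standard_normal((cfg.rows, cfg.cols))
    elev = ndimage.gaussian_filter(rough, sigma=15)
    elev = (elev - elev.min()) / (elev.max() - elev.min() + 1e-12) * 500.0
    elevation = template.like(elev)

    rivers_mask = _make_rivers(cfg, rng)
    rivers = template.like(rivers_mask.astype(np.int32))

    # built seeds biased to low elevation; grown by radial dilation each year
    flat_elev = elev.ravel()
    p = np.exp(-flat_elev / 150.0)
    p /= p.sum()
    seed_idx = rng.choice(flat_elev.size, size=cfg.n_built_seeds, replace=False, p=p)
    seed_mask = np.zeros(flat_elev.size, dtype=bool)
    seed_mask[seed_idx] = True
    seed_mask = seed_mask.reshape(cfg.rows, cfg.cols)
    dist_to_seed = ndimage.distance_transform_edt(~seed_mask, sampling=ps)

    built: dict[str, GridRaster] = {}
    radius0, growth = cfg.built_init_radius_m, cfg.built_growth_m
    for t, year in enumerate(cfg.years):
        radius = radius0 + t * growth
        while True:
            mask = dist_to_seed <= radius
            if mask.mean() <= 0.5:
                break
            radius *= 0.8
            logger.warning("built blobs exceed half the grid; radius shrunk to %.0f m", radius)
        built[year] = template.like(mask.astype(np.int32))

    # lights: brightness rises with the built fraction in a local window
    lights: dict[str, GridRaster] = {}
    for year in cfg.years:
        frac = ndimage.uniform_filter(built[year].values.astype(float),
                                      size=cfg.lights_radius_px)
        vals = np.clip(
            cfg.lights_max * frac + rng.normal(0, cfg.lights_noise, frac.shape),
            0.0, cfg.lights_max,
        )
        lights[year] = template.like(vals)

    # tessellations (before the density draw so the rng stream is stable
    # regardless of how the surfaces are consumed)
    coarse_polys, fine_polys, fine_to_coarse = _tessellate(cfg, template, rng)
    fine_zones = rasterize_zones(fine_polys, template)
    coarse_lookup = np.zeros(max(fine_to_coarse) + 1, dtype=np.int32)
    for fid, cid in fine_to_coarse.items():
        coarse_lookup[fid] = cid
    coarse_vals = np.where(
        fine_zones.values > 0, coarse_lookup[fine_zones.values], 0
    ).astype(np.int32)
    coarse_zones = ZoneRaster(
        values=coarse_vals, origin_x=template.origin_x, origin_y=template.origin_y,
        pixel_size=ps, crs_id=cfg.crs_id,
    )

    # ground-truth density law per year
    true_ppp: dict[str, GridRaster] = {}
    coarse_rows, fine_rows = [], []
    for t, year in enumerate(cfg.years):
        d_km = signed_distance_to_edge(built[year]).values / 1000.0
        beta = cfg.decay_for_year(t)
        log_dens = (
            cfg.log_base_density
            - beta * d_km
            + cfg.lights_coef * (lights[year].values / cfg.lights_max)
            + rng.normal(0, cfg.noise_sigma, (cfg.rows, cfg.cols))
        )
        ppp = np.exp(log_dens)

        # scale each coarse zone so its total is an integer count
        zv = coarse_zones.values
        for cid in np.unique(zv[zv > 0]):
            sel = zv == cid
            total = ppp[sel].sum()
            target = max(1.0, np.round(total))
            ppp[sel] *= target / total
        true_ppp[year] = template.like(ppp)

        for cid in np.unique(zv[zv > 0]):
            coarse_rows.append(
                {"unit_id": int(cid), "population": float(ppp[zv == cid].sum()),
                 "year": year}
            )
        fv = fine_zones.values
        for fid in np.unique(fv[fv > 0]):
            fine_rows.append(
                {"unit_id": int(fid), "population": float(ppp[fv == fid].sum()),
                 "year": year}
            )

    return SyntheticWorld(
        cfg=cfg,
        elevation=elevation,
        rivers=rivers,
        built=built,
        lights=lights,
        true_ppp=true_ppp,
        coarse_polys=coarse_polys,
        fine_polys=fine_polys,
        coarse_zones=coarse_zones,
        fine_zones=fine_zones,
        fine_to_coarse=fine_to_coarse,
        coarse_census=pd.DataFrame(coarse_rows),
        fine_census=pd.DataFrame(fine_rows),
    )


def emit_fixtures(world: SyntheticWorld, out_dir: str | Path) -> dict:
    """Write every raster, vector and census table the pipeline consumes.

    Returns the manifest (also written as ``manifest.json``): config, file
    paths, and the global true population total per year.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = world.cfg
    paths: dict[str, str] = {}

    def _w(name: str, raster: GridRaster) -> None:
        paths[name] = str(write_raster(out / f"{name}.asc", raster))

    _w("elevation", world.elevation)
    _w("rivers", world.rivers)
    for year in cfg.years:
        _w(f"built_{year}", world.built[year])
        _w(f"lights_{year}", world.lights[year])
        _w(f"true_ppp_{year}", world.true_ppp[year])
    _w("coarse_zones", world.coarse_zones)
    _w("fine_zones", world.fine_zones)
    paths["coarse_polys"] = str(write_geojson(out / "coarse_polys.geojson", world.coarse_polys))
    paths["fine_polys"] = str(write_geojson(out / "fine_polys.geojson", world.fine_polys))
    world.coarse_census.to_csv(out / "coarse_census.csv", index=False)
    world.fine_census.to_csv(out / "fine_census.csv", index=False)
    paths["coarse_census"] = str(out / "coarse_census.csv")
    paths["fine_census"] = str(out / "fine_census.csv")

    manifest = {
        "config": asdict(cfg),
        "paths": paths,
        "true_totals": {
            year: float(world.true_ppp[year].values.sum()) for year in cfg.years
        },
        "fine_to_coarse": {str(k): v for k, v in world.fine_to_coarse.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
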