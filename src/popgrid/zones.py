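"""Polygon zone sets: GeoJSON I/O and rasterization to zone-id grids.

Zone sets (administrative units, census tessellations) are lists of
``(unit_id, polygon, attributes)`` in the working projected CRS.  Geometry is
handled by shapely; rasterization assigns each pixel the id of the polygon
containing its center, with ties on shared boundaries broken by the lowest
unit id, which makes the operation deterministic and order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .raster import GridRaster, ZoneRaster


class ZoneError(Exception):
    pass


@dataclass
class ZoneUnit:
    unit_id: int
    polygon: BaseGeometry
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass
class PolygonSet:
    """Set of polygons with unique integer unit ids (>= 1) in one CRS."""

    units: list[ZoneUnit]
    crs_id: str = "local"

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ZoneError("unit ids must be unique")
        if any(i < 1 for i in ids):
            raise ZoneError("unit ids must be >= 1")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[ZoneUnit]:
        return iter(self.units)

    def ids(self) -> list[int]:
        return [u.unit_id for u in self.units]

    def get(self, unit_id: int) -> ZoneUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def repaired(self) -> "PolygonSet":
        """Copy with invalid polygons repaired via buffer(0)/make_valid."""
        units = []
        for u in self.units:
            geom = u.polygon
            if not geom.is_valid:
                geom = make_valid(geom)
            units.append(ZoneUnit(u.unit_id, geom, dict(u.attributes)))
        return PolygonSet(units, self.crs_id)


def read_geojson(path: str | Path, id_property: str = "unit_id",
                 crs_id: str = "local") -> PolygonSet:
    """Read a polygon FeatureCollection; the unit id comes from ``id_property``."""
    obj = json.loads(Path(path).read_text())
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    units = []
    for feat in feats:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ZoneError(f"feature missing id property {id_property!r}")
        geom = shape(feat["geometry"])
        units.append(ZoneUnit(int(props[id_property]), geom,
                              {k: v for k, v in props.items() if k != id_property}))
    return PolygonSet(units, crs_id=obj.get("crs_id", crs_id))


def write_geojson(path: str | Path, polys: PolygonSet,
                  id_property: str = "unit_id") -> Path:
    path = Path(path)
    feats = []
    for u in polys:
        props = {id_property: u.unit_id, **u.attributes}
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(u.polygon)})
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "crs_id": polys.crs_id, "features": feats}))
    return path


def rasterize_zones(polys: PolygonSet, template: GridRaster) -> ZoneRaster:
    """Assign each pixel the id of the polygon containing its center.

    Pixel centers lying exactly on a shared boundary go to the lowest unit id;
    pixels in no polygon are nodata (0).

    Raises
    ------
    ZoneError
        If the set is empty or the CRS differs from the template's.
    """
    if len(polys) == 0:
        raise ZoneError("cannot rasterize an empty PolygonSet")
    if polys.crs_id != template.crs_id:
        raise ZoneError(f"CRS mismatch: {polys.crs_id!r} vs {template.crs_id!r}")

    out = np.zeros(template.shape, dtype=np.int32)
    ps = template.pixel_size
    xs = template.origin_x + (np.arange(template.ncols) + 0.5) * ps
    ys = template.origin_y - (np.arange(template.nrows) + 0.5) * ps

    # Ascending id order + first-assignment-wins realizes the lowest-id tie-break.
    for unit in sorted(polys, key=lambda u: u.unit_id):
        geom = unit.polygon
        if not geom.is_valid:
            geom = make_valid(geom)
        xmin, ymin, xmax, ymax = geom.bounds
        c0 = max(0, int(np.searchsorted(xs, xmin)) - 1)
        c1 = min(template.ncols, int(np.searchsorted(xs, xmax)) + 1)
        r0 = max(0, int(np.searchsorted(-ys, -ymax)) - 1)
        r1 = min(template.nrows, int(np.searchsorted(-ys, -ymin)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        X, Y = np.meshgrid(xs[c0:c1], ys[r0:r1])
        shapely.prepare(geom)
        hit = shapely.intersects_xy(geom, X.ravel(), Y.ravel()).reshape(X.shape)
        window = out[r0:r1, c0:c1]
        window[hit & (window == 0)] = unit.unit_id

    return ZoneRaster(
        values=out,
        origin_x=template.origin_x,
        origin_y=template.origin_y,
        pixel_size=template.pixel_size,
        crs_id=template.crs_id,
    )
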