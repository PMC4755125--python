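"""Per-year covariate stacks for the density model.

The stack for model year *t* holds: the static terrain layers (elevation,
Horn slope, distance to water features), the nighttime-lights composite for
that year, and a signed distance-to-built-edge layer for year *t* **and every
preceding year**.  The lagged built-distance layers let the forest see
settlement history — where built area is old versus newly expanded — instead
of only the contemporaneous extent.

Distances are center-to-center Euclidean in meters on the projected grid:
a built cell carries minus its distance to the nearest non-built cell center,
a non-built cell plus its distance to the nearest built cell center, so the
magnitude is always at least one pixel and zero never occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .raster import GridRaster, align_stack


class CovariateError(Exception):
    pass


@dataclass
class CovariateStack:
    """Named, grid-aligned covariate rasters for one model year."""

    year: str
    layers: dict[str, GridRaster]
    tags: dict[str, str] = field(default_factory=dict)  # 'categorical'|'continuous'

    def __post_init__(self) -> None:
        names = list(self.layers)
        if not names:
            raise CovariateError("stack must contain at least one layer")
        ref = self.layers[names[0]]
        for name in names[1:]:
            if not self.layers[name].same_grid(ref):
                raise CovariateError(f"layer {name!r} is not grid-aligned with {names[0]!r}")
        for name in names:
            self.tags.setdefault(name, "continuous")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> GridRaster:
        return next(iter(self.layers.values()))

    def usable_mask(self) -> np.ndarray:
        """True where every layer holds data; nodata anywhere marks the pixel unusable."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.data_mask
        return mask

    def as_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_pixels, n_layers) matrix of layer values at masked pixels (row-major)."""
        if mask is None:
            mask = self.usable_mask()
        return np.column_stack([self.layers[n].values[mask] for n in self.names])


def _check_binary(raster: GridRaster, what: str) -> np.ndarray:
    vals = raster.values
    mask = raster.data_mask
    ok = np.isin(vals[mask], (0, 1))
    if not bool(np.all(ok)):
        raise CovariateError(f"{what} raster must contain only {{0, 1, nodata}}")
    return vals == 1


def signed_distance_to_edge(built: GridRaster) -> GridRaster:
    """Signed Euclidean distance (m) to the built land-cover edge.

    Negative inside the built class, positive outside; nodata propagated.

    Raises
    ------
    CovariateError
        If the mask is all-built or all-non-built (the edge is undefined),
        or not binary.
    """
    is_built = _check_binary(built, "built")
    data = built.data_mask
    n_built = int(np.count_nonzero(is_built & data))
    n_open = int(np.count_nonzero(~is_built & data))
    if n_built == 0 or n_open == 0:
        raise CovariateError("built mask needs at least one built and one non-built cell")

    ps = built.pixel_size
    # Distance of each non-zero cell of the input to the nearest zero cell:
    dist_to_built = ndimage.distance_transform_edt(~(is_built & data), sampling=ps)
    dist_to_open = ndimage.distance_transform_edt(~(~is_built & data), sampling=ps)
    signed = np.where(is_built, -dist_to_open, dist_to_built)
    signed = np.where(data, signed, built.nodata)
    return built.like(signed, nodata=built.nodata)


def distance_to_features(features: GridRaster) -> GridRaster:
    """Euclidean distance (m) to the nearest feature cell; feature cells are 0."""
    is_feat = _check_binary(features, "features")
    data = features.data_mask
    if not np.any(is_feat & data):
        raise CovariateError("no feature cells present")
    ps = features.pixel_size
    dist = ndimage.distance_transform_edt(~(is_feat & data), sampling=ps)
    dist = np.where(data, dist, features.nodata)
    return features.like(dist, nodata=features.nodata)


# Horn (1981) 3x3 kernels; denominators fold in the 8x weighting.
_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_HORN_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


def slope_from_elevation(dem: GridRaster) -> GridRaster:
    """Slope in degrees from elevation via the Horn 3x3 estimator.

    Border cells use edge replication.  Requires a DEM of at least 3x3 cells.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise CovariateError("DEM must be at least 3x3")
    z = dem.values.astype(float)
    ps = dem.pixel_size
    dzdx = ndimage.convolve(z, _HORN_X[:, ::-1], mode="nearest") / (8.0 * ps)
    dzdy = ndimage.convolve(z, _HORN_Y[::-1, :], mode="nearest") / (8.0 * ps)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope = np.where(dem.data_mask, slope, dem.nodata)
    return dem.like(slope)


def composite_lights(rasters: Sequence[GridRaster]) -> GridRaster:
    """Cellwise mean of aligned lights rasters (e.g. the two satellites of one year).

    A cell is nodata iff it is nodata in any input.
    """
    rasters = list(rasters)
    if not rasters:
        raise CovariateError("need at least one lights raster")
    ref = rasters[0]
    for r in rasters[1:]:
        if not r.same_grid(ref):
            raise CovariateError("lights rasters must be grid-aligned")
    if len(rasters) == 1:
        return ref.copy()
    stack = np.stack([np.where(r.data_mask, r.values.astype(float), np.nan) for r in rasters])
    mean = stack.mean(axis=0)
    out = np.where(np.isfinite(mean), mean, ref.nodata)
    return ref.like(out)


def build_stack(
    year_index: int,
    years: Sequence[str],
    static: Mapping[str, GridRaster],
    lights: Mapping[str, GridRaster],
    built: Mapping[str, GridRaster],
    align: bool = True,
) -> CovariateStack:
    """Assemble the covariate stack for ``years[year_index]``.

    Layer order is deterministic: static layers in the given order, then
    ``lights``, then ``built_dist_<year>`` for every year up to and including
    the model year, oldest first.  ``built`` maps each year label to its
    binary built-extent mask; a missing year raises.
    """
    if not 0 <= year_index < len(years):
        raise CovariateError(f"year_index {year_index} outside years {list(years)}")
    year = years[year_index]
    needed = list(years[: year_index + 1])
    missing = [y for y in needed if y not in built]
    if missing:
        raise CovariateError(f"missing built masks for years {missing}")
    if year not in lights:
        raise CovariateError(f"missing lights raster for year {year!r}")

    layers: dict[str, GridRaster] = {}
    tags: dict[str, str] = {}
    for name, r in static.items():
        layers[name] = r
        tags[name] = "continuous"
    layers["lights"] = lights[year]
    tags["lights"] = "continuous"
    for y in needed:
        name = f"built_dist_{y}"
        layers[name] = signed_distance_to_edge(built[y])
        tags[name] = "continuous"

    if align:
        names = list(layers)
        aligned = align_stack([layers[n] for n in names],
                              categorical=[tags[n] == "categorical" for n in names])
        layers = dict(zip(names, aligned))
    return CovariateStack(year=year, layers=layers, tags=tags)
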