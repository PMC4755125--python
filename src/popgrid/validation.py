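"""Validation of gridded population against finer census units.

The gridded surface is summed within validation zones (a finer tessellation
than the model's units) and compared with the observed counts there.  Metrics
follow the standard gridded-population validation suite:

* RMSE — root mean square error of per-unit counts,
* RMSE/Area — RMSE of per-unit *densities* (count / pixel count), which
  controls for unit size; on the counts scale this equals the RMSE one gets
  by rerunning the metrics on densities,
* %RMSE — RMSE as a percentage of the mean observed count (optionally of the
  grand total, behind a switch),
* MAE — mean absolute error, less outlier-sensitive than RMSE,
* MAD — median absolute error, robust to the few huge errors that dominate
  skewed count distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .dasymetric import PopulationRaster
from .zones import ZoneRaster

logger = logging.getLogger(__name__)


class ValidationError(Exception):
    pass


@dataclass
class ValidationMetrics:
    rmse: float
    mae: float
    mad: float
    pct_rmse: float | None
    rmse_per_area: float | None
    n_units: int
    scale: str  # 'counts' | 'densities'

    def __post_init__(self) -> None:
        for name in ("rmse", "mae", "mad"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.mae > self.rmse + 1e-12:
            raise ValidationError("MAE cannot exceed RMSE")
        if self.mad > self.rmse + 1e-12:
            raise ValidationError("MAD cannot exceed RMSE")

    def to_dict(self) -> dict:
        return asdict(self)


def aggregate_to_units(
    pop: PopulationRaster, val_zones: ZoneRaster
) -> pd.DataFrame:
    """Sum the ppp surface within each validation zone.

    Returns a frame with ``zone_id, predicted, pixel_count``; zones with no
    pixel on the grid are excluded (they cannot receive mass) and logged.
    """
    if not val_zones.same_grid(pop.ppp):
        raise ValidationError("validation zones must share the population grid")
    zvals = val_zones.values
    mask = val_zones.data_mask
    ppp = np.where(pop.ppp.data_mask, pop.ppp.values, 0.0)
    flat_z = zvals[mask]
    ids = val_zones.zone_ids()
    id_to_idx = {int(z): i for i, z in enumerate(ids)}
    idx = np.array([id_to_idx[int(z)] for z in flat_z])
    sums = np.bincount(idx, weights=ppp[mask], minlength=len(ids))
    npix = np.bincount(idx, minlength=len(ids))
    return pd.DataFrame(
        {"zone_id": [int(z) for z in ids], "predicted": sums, "pixel_count": npix}
    )


def unit_density(count: float | np.ndarray, pixel_count: int | np.ndarray):
    """Population density as people per pixel: count / pixel_count."""
    pixel_count = np.asarray(pixel_count)
    if np.any(pixel_count < 1):
        raise ValidationError("pixel_count must be >= 1")
    return np.asarray(count) / pixel_count


def error_metrics(
    obs,
    pred,
    pixel_counts=None,
    scale: str = "counts",
    pct_denominator: Literal["unit_mean", "grand_total"] = "unit_mean",
) -> ValidationMetrics:
    """Error metrics between observed and predicted per-unit values.

    Parameters
    ----------
    obs, pred : array-like, same length
        Observed and predicted counts (or densities, with ``scale``).
    pixel_counts : array-like, optional
        Pixels per unit; enables RMSE/Area (the RMSE of density errors).
    scale : 'counts' or 'densities'
        Label recorded in the result.
    pct_denominator
        Denominator of %RMSE: the mean observed value per unit (default) or
        the grand total of observations.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise ValidationError("obs and pred must be equal-length 1-D vectors")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mad = float(np.median(np.abs(err)))

    denom = float(np.mean(obs)) if pct_denominator == "unit_mean" else float(np.sum(obs))
    if denom == 0:
        logger.warning("%%RMSE undefined: zero observed denominator")
        pct_rmse = None
    else:
        pct_rmse = 100.0 * rmse / denom

    rmse_per_area = None
    if pixel_counts is not None:
        pixel_counts = np.asarray(pixel_counts, dtype=float)
        if np.any(pixel_counts <= 0):
            raise ValidationError("pixel_counts must be > 0")
        rmse_per_area = float(np.sqrt(np.mean((err / pixel_counts) ** 2)))

    return ValidationMetrics(
        rmse=rmse, mae=mae, mad=mad, pct_rmse=pct_rmse,
        rmse_per_area=rmse_per_area, n_units=obs.size, scale=scale,
    )


def validation_summary(
    obs_counts,
    pred_counts,
    pixel_counts,
    pct_denominator: Literal["unit_mean", "grand_total"] = "unit_mean",
) -> dict[str, ValidationMetrics]:
    """Metrics on both scales: unit counts and unit densities.

    The counts-scale RMSE/Area coincides with the densities-scale RMSE by
    construction (both are the RMSE of per-unit density errors).
    """
    counts = error_metrics(obs_counts, pred_counts, pixel_counts,
                           scale="counts", pct_denominator=pct_denominator)
    obs_d = unit_density(np.asarray(obs_counts, dtype=float), pixel_counts)
    pred_d = unit_density(np.asarray(pred_counts, dtype=float), pixel_counts)
    densities = error_metrics(obs_d, pred_d, None, scale="densities",
                              pct_denominator=pct_denominator)
    return {"counts": counts, "densities": densities}
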