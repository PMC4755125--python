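"""Random-forest log-density model fitted per census year.

The response is the natural log of census-unit population density, people per
usable pixel: ``log_density = ln(count / pixel_count)``.  Predictors are
zonal means of the covariate stack.  The forest follows the classic bagged
regression-tree recipe: 500 bootstrap trees grown unpruned to
single-observation terminal nodes with **all** covariates candidates at every
split, so each tree is a fully-grown bootstrap replicate and regularization
comes from the ensemble average alone.

Out-of-bag (OOB) machinery is first-class here: each observation is predicted
by the trees whose bootstrap sample excluded it, giving an honest error
estimate (OOB mean squared error on the log scale, and the derived variance
explained) plus Breiman-style permutation importance — for each covariate,
its values are permuted among the OOB cases of each tree and the percent
increase in OOB MSE measures how much the fit relies on it.

Each census year gets its own independent fit; the pixel-level surface
``exp(forest prediction)`` is used downstream as the dasymetric weighting
layer, where any constant multiplicative bias cancels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, check_random_state

from .covariates import CovariateStack
from .harmonize import HarmonizedCensus
from .raster import GridRaster
from .zones import ZoneRaster

logger = logging.getLogger(__name__)

NON_COVARIATE_COLUMNS = ("zone_id", "pixel_count", "area_ha", "count", "log_density")


class DensityModelError(Exception):
    pass


def zonal_summarize(
    stack: CovariateStack,
    zones: ZoneRaster,
    census: HarmonizedCensus,
) -> pd.DataFrame:
    """Per-zone covariate means, pixel counts and log population density.

    A pixel is usable when it holds data in every stack layer.  Zones with no
    usable pixel or with zero count are excluded (log density undefined) and
    logged; they still receive pixel-level predictions later.

    Returns a ZonalTable: one row per retained zone with columns
    ``zone_id, pixel_count, area_ha, <covariate means...>, count, log_density``.

    Raises
    ------
    DensityModelError
        If a zone with usable pixels has no census count.
    """
    if not zones.same_grid(stack.grid):
        raise DensityModelError("zones raster is not aligned with the covariate stack")
    usable = stack.usable_mask() & zones.data_mask
    zvals = zones.values[usable]
    X = stack.as_matrix(usable)

    order = np.argsort(zvals, kind="stable")
    zsorted = zvals[order]
    uniq, starts = np.unique(zsorted, return_index=True)
    sums = np.add.reduceat(X[order], starts, axis=0)
    npix = np.diff(np.append(starts, zsorted.size))

    pixel_area_ha = zones.pixel_size**2 / 10_000.0
    rows = []
    missing = [int(z) for z in uniq if int(z) not in census.counts]
    if missing:
        raise DensityModelError(f"zones with pixels but no census count: {missing[:10]}")
    for i, zid in enumerate(uniq):
        zid = int(zid)
        count = census.counts[zid]
        n = int(npix[i])
        if count <= 0:
            logger.info("zone %d excluded from fitting: zero count", zid)
            continue
        row = {"zone_id": zid, "pixel_count": n, "area_ha": n * pixel_area_ha}
        for j, name in enumerate(stack.names):
            row[name] = sums[i, j] / n
        row["count"] = float(count)
        row["log_density"] = float(np.log(count / n))
        rows.append(row)
    excluded = set(int(z) for z in zones.zone_ids()) - {r["zone_id"] for r in rows}
    if excluded:
        logger.info("%d zones excluded from the zonal table", len(excluded))
    cols = ["zone_id", "pixel_count", "area_ha", *stack.names, "count", "log_density"]
    return pd.DataFrame(rows, columns=cols)


def covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in NON_COVARIATE_COLUMNS]


class DensityForest(BaseEstimator, RegressorMixin):
    """Bagged regression forest with exact per-tree out-of-bag bookkeeping.

    Parameters
    ----------
    n_estimators : int, default 500
        Trees in the forest.
    min_samples_leaf : int, default 1
        Observations per terminal node; 1 grows each tree out fully.
    max_features : int, float or None, default None
        Covariates considered per split; None means all of them.
    min_rows : int, default 20
        Minimum training rows; a forest on fewer census units is refused.
    random_state : int or None
        Seeds the bootstrap and the trees; fits are bit-reproducible given it.

    Attributes
    ----------
    estimators_ : list of DecisionTreeRegressor
    oob_indices_ : list of ndarray
        For each tree, the row indices excluded from its bootstrap sample.
    oob_prediction_ : ndarray of shape (n_samples,)
        Mean prediction over the trees not containing each row.
    oob_mse_ : float
        Mean squared OOB residual (log-density scale).
    oob_variance_explained_ : float or nan
        ``1 - oob_mse_ / var(y)``; nan when the response is constant.
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        min_samples_leaf: int = 1,
        max_features: int | float | None = None,
        min_rows: int = 20,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.min_rows = min_rows
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if p < 1:
            raise ValueError("need at least one covariate")
        if n < self.min_rows:
            raise DensityModelError(
                f"need at least {self.min_rows} rows to fit the forest, got {n}"
            )
        if y.shape != (n,):
            raise ValueError("y length must match X rows")
        rng = check_random_state(self.random_state)
        max_features = self.max_features if self.max_features is not None else p

        self.n_features_in_ = p
        self.estimators_ = []
        self.oob_indices_ = []
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n, dtype=int)
        for _ in range(self.n_estimators):
            boot = rng.randint(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeRegressor(
                min_samples_leaf=self.min_samples_leaf,
                max_features=max_features,
                random_state=rng.randint(np.iinfo(np.int32).max),
            )
            tree.fit(X[boot], y[boot])
            self.estimators_.append(tree)
            self.oob_indices_.append(oob)
            if oob.size:
                oob_sum[oob] += tree.predict(X[oob])
                oob_cnt[oob] += 1

        covered = oob_cnt > 0
        if not covered.all():
            logger.warning(
                "%d rows never out-of-bag; their OOB prediction falls back to the mean response",
                int((~covered).sum()),
            )
        self.oob_prediction_ = np.where(covered, oob_sum / np.maximum(oob_cnt, 1), y.mean())
        resid = self.oob_prediction_ - y
        self.oob_mse_ = float(np.mean(resid**2))
        var_y = float(np.var(y))
        self.oob_variance_explained_ = (
            1.0 - self.oob_mse_ / var_y if var_y > 0 else float("nan")
        )
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise DensityModelError(f"missing covariates: {missing}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for tree in self.estimators_:
            out += tree.predict(X)
        return out / len(self.estimators_)

    def permutation_importance(
        self,
        n_repeats: int = 5,
        random_state: int | None = None,
        _identity: bool = False,
    ) -> dict[str, float]:
        """Percent increase in OOB MSE when each covariate is permuted.

        For each tree, the covariate's values are shuffled among that tree's
        out-of-bag cases before predicting; the resulting OOB MSE is compared
        with the unpermuted one and ``100 * (MSE_perm - MSE_orig) / MSE_orig``
        is averaged over ``n_repeats`` independent shuffles.

        The ``_identity`` hook replaces the shuffle with the identity
        permutation (importance is then exactly zero); it exists for testing
        the bookkeeping.
        """
        check_is_fitted(self, "estimators_")
        rng = check_random_state(random_state)
        X, y = self.X_, self.y_
        n = X.shape[0]
        names = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"x{j}" for j in range(self.n_features_in_)]
        )
        mse_orig = self.oob_mse_
        importances = {}
        for j, name in enumerate(names):
            incs = []
            for _ in range(n_repeats):
                oob_sum = np.zeros(n)
                oob_cnt = np.zeros(n, dtype=int)
                for tree, oob in zip(self.estimators_, self.oob_indices_):
                    if oob.size == 0:
                        continue
                    Xp = X[oob].copy()
                    if not _identity:
                        Xp[:, j] = Xp[rng.permutation(oob.size), j]
                    oob_sum[oob] += tree.predict(Xp)
                    oob_cnt[oob] += 1
                covered = oob_cnt > 0
                pred = np.where(covered, oob_sum / np.maximum(oob_cnt, 1), y.mean())
                mse_perm = float(np.mean((pred - y) ** 2))
                incs.append(100.0 * (mse_perm - mse_orig) / mse_orig)
            importances[name] = float(np.mean(incs))
        return importances


# -- functional wrappers over the estimator --------------------------------

def fit_forest(
    table: pd.DataFrame,
    seed: int | None = None,
    n_estimators: int = 500,
    min_samples_leaf: int = 1,
    max_features: int | float | None = None,
) -> DensityForest:
    """Fit the per-year density forest on a ZonalTable."""
    cols = covariate_columns(table)
    if not cols:
        raise DensityModelError("zonal table has no covariate columns")
    model = DensityForest(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        max_features=max_features,
        random_state=seed,
    )
    return model.fit(table[cols], table["log_density"].to_numpy())


def oob_error(model: DensityForest, table: pd.DataFrame | None = None) -> tuple[float, float]:
    """(OOB MSE on log density, OOB variance explained) of a fitted forest."""
    check_is_fitted(model, "estimators_")
    return model.oob_mse_, model.oob_variance_explained_


def permutation_importance(
    model: DensityForest,
    table: pd.DataFrame | None = None,
    n_repeats: int = 5,
    seed: int | None = None,
) -> dict[str, float]:
    return model.permutation_importance(n_repeats=n_repeats, random_state=seed)


def predict_density_surface(model: DensityForest, stack: CovariateStack) -> GridRaster:
    """Pixel-level weighting layer: exp(forest prediction) on usable pixels.

    Unusable pixels (nodata in any covariate) are nodata in the output; the
    exponential back-transform makes the surface strictly positive wherever
    defined.  Layer names must match the model's covariates exactly.
    """
    check_is_fitted(model, "estimators_")
    names = stack.names
    model_names = (
        list(model.feature_names_in_)
        if hasattr(model, "feature_names_in_")
        else None
    )
    if model_names is not None and model_names != names:
        raise DensityModelError(
            f"stack layers {names} do not match model covariates {model_names}"
        )
    usable = stack.usable_mask()
    X = stack.as_matrix(usable)
    grid = stack.grid
    out = np.full(grid.shape, grid.nodata, dtype=float)
    if X.shape[0]:
        out[usable] = np.exp(model.predict(X))
    return GridRaster(
        values=out,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        pixel_size=grid.pixel_size,
        crs_id=grid.crs_id,
        nodata=grid.nodata,
    )
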