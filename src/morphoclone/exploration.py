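"""Descriptive analyses: size-distribution KDEs, profile PCA, scalar R^2.

These reproduce the exploratory views of the cohort: Gaussian kernel
density estimates of the log10 cell-area distribution (after discarding
small, round, proliferating objects below 200 px), principal-component
maps of clone profiles (optionally with bootstrap replicate clouds
projected onto axes fitted on a merged dataset), the squared Pearson
correlation between a per-clone scalar (e.g. growth rate) and potency,
and two-sample t-tests between descriptor populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .profiling import MorphologicalProfile

#: pixel-area filter for the size-distribution analysis: objects at or
#: below this are mostly rounded-up proliferating cells, not spread cells
MIN_AREA_PX_FILTER = 200


@dataclass
class DensityEstimate:
    """Gaussian KDE of log10 cell area, with filter bookkeeping."""

    grid: np.ndarray          # log10(area_px) evaluation points
    density: np.ndarray
    bandwidth: float
    n_used: int
    n_filtered: int
    min_area_px: int
    median_area_um2: float

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def kde_log_area(cells: pd.DataFrame, min_area_px: int = MIN_AREA_PX_FILTER,
                 bandwidth: str | float = "silverman",
                 grid_points: int = 512,
                 pixel_size: float | None = None) -> DensityEstimate:
    """KDE of log10(area_px) over cells with area_px > ``min_area_px``.

    The evaluation grid spans the data range extended by three bandwidths.
    The median area is reported in um^2 when ``pixel_size`` is given (or a
    ``Area`` column is present), else in pixel units.
    """
    area_px = cells["area_px"].to_numpy(dtype=np.float64)
    keep = area_px > min_area_px
    n_used, n_filtered = int(keep.sum()), int((~keep).sum())
    if n_used < 10:
        raise ValueError(
            f"only {n_used} cells survive the area > {min_area_px} px filter; "
            "need >= 10 for a density estimate")
    x = np.log10(area_px[keep])
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    bw = float(kde.factor * x.std(ddof=1))
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    if pixel_size is not None:
        median_area = float(np.median(area_px[keep])) * pixel_size ** 2
    elif "Area" in cells.columns:
        median_area = float(cells.loc[keep, "Area"].median())
    else:
        median_area = float(np.median(area_px[keep]))
    return DensityEstimate(grid=grid, density=dens, bandwidth=bw,
                           n_used=n_used, n_filtered=n_filtered,
                           min_area_px=min_area_px,
                           median_area_um2=median_area)


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a profile PCA."""

    scores: pd.DataFrame            # rows = profiles, cols = PC1..PCk
    loadings: pd.DataFrame          # rows = parameters, cols = PC1..PCk
    explained_variance_ratio: np.ndarray
    meta: pd.DataFrame              # clone_id, replicate_id, color key values
    dropped_parameters: list[str] = field(default_factory=list)


class ProfilePCA(BaseEstimator, TransformerMixin):
    """PCA of z-scored morphological profiles with a fixed sign convention.

    Fit on a merged dataset to set common axes, then ``transform``
    subsets (e.g. per-FOV-count variants or bootstrap clouds) onto those
    fixed axes. Constant parameter columns are dropped with a warning.
    The sign of each component is fixed so its largest-magnitude loading
    is positive, making scores reproducible across runs.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        X = _profiles_matrix(X)
        keep = X.std(ddof=0) > 0
        self.dropped_ = [str(c) for c in X.columns[~keep]]
        if self.dropped_:
            warnings.warn(f"dropping {len(self.dropped_)} constant parameter "
                          f"column(s): {self.dropped_[:3]}...", stacklevel=2)
        X = X.loc[:, keep]
        self.columns_ = [str(c) for c in X.columns]
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        n_comp = self.n_components or min(Z.shape)
        self.pca_ = PCA(n_components=min(n_comp, min(Z.shape))).fit(Z)
        # sign convention: largest-|loading| entry of each component > 0
        comps = self.pca_.components_
        flips = np.sign(comps[np.arange(comps.shape[0]),
                              np.argmax(np.abs(comps), axis=1)])
        flips[flips == 0] = 1.0
        self.flips_ = flips
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "pca_")
        X = _profiles_matrix(X)[self.columns_]
        return self.pca_.transform(self.scaler_.transform(X)) * self.flips_

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self.pca_.explained_variance_ratio_

    def loadings(self) -> pd.DataFrame:
        check_is_fitted(self, "pca_")
        comps = (self.pca_.components_ * self.flips_[:, None]).T
        return pd.DataFrame(comps, index=self.columns_,
                            columns=[f"PC{i+1}" for i in range(comps.shape[1])])


def _profiles_matrix(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    profiles: Sequence[MorphologicalProfile] = list(X)
    return pd.DataFrame([p.values for p in profiles],
                        columns=profiles[0].names)


def pca_profiles(profiles: Sequence[MorphologicalProfile],
                 color_key: str = "clone_id",
                 n_components: int | None = None) -> PcaResult:
    """PCA of a set of profiles (fit and score the same set)."""
    profiles = list(profiles)
    if len(profiles) < 3:
        raise ValueError(f"need >= 3 profiles, got {len(profiles)}")
    model = ProfilePCA(n_components=n_components).fit(profiles)
    scores = model.transform(profiles)
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    meta = pd.DataFrame({
        "clone_id": [p.clone_id for p in profiles],
        "replicate_id": [p.replicate_id for p in profiles]})
    return PcaResult(
        scores=pd.DataFrame(scores, columns=cols),
        loadings=model.loadings(),
        explained_variance_ratio=model.explained_variance_ratio_,
        meta=meta, dropped_parameters=model.dropped_)


def scalar_r2(x: Iterable[float], y: Iterable[float]) -> float:
    """Coefficient of determination (squared Pearson r) of two scalars."""
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: R^2 undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def compare_distributions(a: pd.DataFrame, b: pd.DataFrame,
                          descriptor: str) -> tuple[float, float]:
    """Two-sample Student's t-test on one descriptor between two cohorts.

    Returns ``(statistic, p_value)``.
    """
    xa = a[descriptor].to_numpy(dtype=np.float64)
    xb = b[descriptor].to_numpy(dtype=np.float64)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs >= 2 records")
    if xa.std() == 0 and xb.std() == 0:
        if np.isclose(xa.mean(), xb.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return float(t), float(p)
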