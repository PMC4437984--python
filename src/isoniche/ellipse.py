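"""Standard ellipse fitting for bivariate isotopic niches.

The standard ellipse of a (δ13C, δ15N) point cloud is the Mahalanobis
distance² = 1 contour of the fitted bivariate normal: the bivariate analogue
of the standard deviation.  Its area

    SEA = π·a·b = π·√(λ1·λ2),

with λ1 ≥ λ2 the eigenvalues of the sample covariance (divisor n−1), contains
≈ 1 − e^(−1/2) ≈ 39.35% of normally distributed data — the "core" niche.  The
small-sample-corrected area is SEAc = SEA·(n−1)/(n−2), i.e. an effective n−2
divisor to account for estimating two dimensions.  Ellipse shape is summarised
by the eccentricity √(1 − λ2/λ1) ∈ [0, 1) and the major-axis angle.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .io import DegenerateDataError, SpeciesDataset, as_dataset

_SING_TOL = 1e-12


class StandardEllipse(BaseEstimator):
    """Fit the standard (1-SD Mahalanobis) ellipse of a bivariate point cloud.

    Parameters
    ----------
    standardize : bool, default False
        If True, z-score each axis before fitting.  With no explicit
        ``center``/``scale`` the fitted sample's own moments are used
        (per-species standardization); passing pooled community moments gives
        the community-reference standardization used to compare ellipse
        shapes across isotopes with unequal fractionation spread.
    center, scale : length-2 sequences, optional
        Explicit standardization reference (mean and SD per axis).  Ignored
        unless ``standardize`` is True.

    Attributes
    ----------
    location_ : (2,) ndarray — centroid (mean δ13C, mean δ15N), post-standardization.
    covariance_ : (2, 2) ndarray — unbiased sample covariance (divisor n−1).
    eigenvalues_ : (2,) ndarray — (λ1, λ2), descending.
    semi_axes_ : (2,) ndarray — (a, b) = (√λ1, √λ2).
    rotation_ : float — major-axis angle vs the δ13C axis, in (−π/2, π/2].
    sea_ : float — standard ellipse area, ‰².
    seac_ : float — small-sample-corrected area SEA·(n−1)/(n−2), ‰².
    eccentricity_ : float — √(1 − λ2/λ1) ∈ [0, 1).
    n_samples_ : int
    """

    def __init__(self, standardize: bool = False, center=None, scale=None):
        self.standardize = standardize
        self.center = center
        self.scale = scale

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        X = _as_xy(X)
        n = X.shape[0]
        if n < 3:
            raise DegenerateDataError(f"standard ellipse requires n >= 3 points, got {n}")
        if self.standardize:
            c = np.mean(X, axis=0) if self.center is None else np.asarray(self.center, dtype=float)
            s = np.std(X, axis=0, ddof=1) if self.scale is None else np.asarray(self.scale, dtype=float)
            if np.any(s <= 0):
                raise DegenerateDataError("zero spread on an axis; cannot standardize")
            X = (X - c) / s
            self.standardize_center_, self.standardize_scale_ = c, s
        self.location_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        lam, vec = np.linalg.eigh(cov)  # ascending
        if lam[0] <= _SING_TOL * max(lam[1], 1.0):
            raise DegenerateDataError("singular covariance: points are (nearly) collinear")
        order = [1, 0]
        lam, vec = lam[order], vec[:, order]
        self.covariance_ = cov
        self.eigenvalues_ = lam
        self.semi_axes_ = np.sqrt(lam)
        # major-axis angle folded into (−π/2, π/2]
        ang = np.arctan2(vec[1, 0], vec[0, 0])
        if ang <= -np.pi / 2:
            ang += np.pi
        elif ang > np.pi / 2:
            ang -= np.pi
        self.rotation_ = float(ang)
        self.n_samples_ = n
        self.sea_ = float(np.pi * np.sqrt(lam[0] * lam[1]))
        self.seac_ = self.sea_ * (n - 1) / (n - 2)
        self.eccentricity_ = float(np.sqrt(1.0 - lam[1] / lam[0]))
        return self

    # -- geometry ---------------------------------------------------------

    def mahalanobis_sq(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of points from the fitted centroid."""
        _check_fitted(self)
        X = _as_xy(X)
        if self.standardize:
            X = (X - self.standardize_center_) / self.standardize_scale_
        d = X - self.location_
        sol = np.linalg.solve(self.covariance_, d.T)
        return np.einsum("ij,ji->i", d, sol)

    def fraction_within(self, X) -> float:
        """Proportion of points inside the standard ellipse (Mahalanobis² ≤ 1)."""
        return float(np.mean(self.mahalanobis_sq(X) <= 1.0))

    def boundary(self, vertices: int = 1024, scale: str = "seac") -> np.ndarray:
        """Polygonal discretization of the ellipse boundary.

        Vertices are placed at uniform parametric angles and radially
        inflated so the polygon's shoelace area equals the requested ellipse
        area exactly (``scale='sea'`` or ``'seac'``).
        """
        _check_fitted(self)
        if vertices < 3:
            raise ValueError("need at least 3 vertices")
        area = {"sea": self.sea_, "seac": self.seac_}[scale]
        a, b = self.semi_axes_ * np.sqrt(area / self.sea_)
        theta = np.linspace(0.0, 2.0 * np.pi, vertices, endpoint=False)
        # inscribed-polygon area = (N/2)·a·b·sin(2π/N); inflate to match the ellipse
        inflate = np.sqrt(2.0 * np.pi / vertices / np.sin(2.0 * np.pi / vertices))
        unit = np.column_stack([a * np.cos(theta), b * np.sin(theta)]) * inflate
        c, s = np.cos(self.rotation_), np.sin(self.rotation_)
        rot = np.array([[c, -s], [s, c]])
        return unit @ rot.T + self.location_


def fit_standard_ellipse(points, standardize: bool = False, center=None, scale=None) -> StandardEllipse:
    """Functional wrapper: fit a :class:`StandardEllipse` to a dataset/array."""
    return StandardEllipse(standardize=standardize, center=center, scale=scale).fit(points)


def eccentricity_of(ellipse: StandardEllipse) -> float:
    """√(1 − (b/a)²) of a fitted ellipse; 0 iff the covariance is isotropic."""
    _check_fitted(ellipse)
    return ellipse.eccentricity_


def fraction_within(points, ellipse: StandardEllipse) -> float:
    """Proportion of ``points`` inside the fitted standard ellipse."""
    return ellipse.fraction_within(points)


def pooled_moments(datasets: list[SpeciesDataset]) -> tuple[np.ndarray, np.ndarray]:
    """Community-pooled per-axis mean and SD (all species' points together)."""
    xy = np.vstack([as_dataset(d).xy for d in datasets])
    return xy.mean(axis=0), xy.std(axis=0, ddof=1)


def community_ellipses(
    datasets: list[SpeciesDataset], standardize: str = "none"
) -> dict[str, StandardEllipse]:
    """Fit per-species standard ellipses across a community.

    ``standardize`` is ``'none'``, ``'pooled'`` (z-score each axis by the
    pooled community moments, the default reference for eccentricity
    comparisons), or ``'species'`` (each species z-scored by its own moments).
    """
    if standardize not in ("none", "pooled", "species"):
        raise ValueError("standardize must be 'none', 'pooled' or 'species'")
    kwargs: dict = {}
    if standardize == "pooled":
        center, scale = pooled_moments(datasets)
        kwargs = dict(standardize=True, center=center, scale=scale)
    elif standardize == "species":
        kwargs = dict(standardize=True)
    return {as_dataset(d).species: fit_standard_ellipse(as_dataset(d), **kwargs) for d in datasets}


def _as_xy(X) -> np.ndarray:
    if isinstance(X, SpeciesDataset):
        return X.xy
    if hasattr(X, "columns"):
        return as_dataset(X).xy
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (d13C, d15N) points")
    if not np.all(np.isfinite(X)):
        raise ValueError("points must be finite")
    return X


def _check_fitted(est):
    if not hasattr(est, "covariance_"):
        raise RuntimeError("ellipse is not fitted; call fit() first")
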