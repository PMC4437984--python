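"""Bayesian posterior sampling of niche area (SEA_B) and pairwise comparisons.

The covariance of each species' (δ13C, δ15N) cloud gets a conjugate
normal–inverse-Wishart posterior under a weakly informative prior (prior mean
at the sample mean, precision scale κ0 = 1e-3, ν0 = 3 degrees of freedom,
scale matrix 1e-3·I).  Each posterior draw Σ yields one niche-area draw
π·√(det Σ); SEA_B is the mean of the draws.  At field sample sizes (n ≥ 55
here) the posterior is data-dominated and SEA_B tracks SEAc closely.

Pairwise niche-size probabilities are Monte-Carlo: the fraction of draw
indices at which one species' area is below another's, arranged in the
rows-smaller / columns-larger matrix layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import DegenerateDataError
from .ellipse import _as_xy


class BayesianNiche(BaseEstimator):
    """Posterior of the standard-ellipse niche area under a conjugate NIW model.

    Parameters
    ----------
    n_draws : int, default 10000
        Posterior Monte-Carlo draws (MC SE of a comparison probability
        ≈ 0.005, adequate for two-decimal reporting).
    kappa0, nu0, psi0_scale : floats
        Normal–inverse-Wishart prior hyperparameters; defaults are weakly
        informative (κ0 = 1e-3, ν0 = 3, Ψ0 = 1e-3·I) with prior mean fixed at
        the sample mean.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    draws_ : (n_draws,) ndarray of SEA draws (‰²), all positive.
    sea_b_ : float — posterior mean niche area.
    credible_interval_ : (lower, upper) central 95% interval.
    n_samples_ : int
    """

    def __init__(self, n_draws: int = 10_000, kappa0: float = 1e-3, nu0: float = 3.0,
                 psi0_scale: float = 1e-3, random_state=None):
        self.n_draws = n_draws
        self.kappa0 = kappa0
        self.nu0 = nu0
        self.psi0_scale = psi0_scale
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_xy(X)
        n = X.shape[0]
        if n < 3:
            raise DegenerateDataError(f"posterior sampling requires n >= 3, got {n}")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        scatter = np.cov(X, rowvar=False, ddof=1) * (n - 1)
        if np.linalg.det(scatter) <= 0:
            raise DegenerateDataError("degenerate (collinear) data; covariance posterior undefined")
        # conjugate update; the mean-offset term vanishes because μ0 = x̄
        nu_n = self.nu0 + n
        psi_n = self.psi0_scale * np.eye(2) + scatter
        rng = np.random.default_rng(self.random_state)
        sigmas = stats.invwishart.rvs(df=nu_n, scale=psi_n, size=self.n_draws, random_state=rng)
        dets = sigmas[:, 0, 0] * sigmas[:, 1, 1] - sigmas[:, 0, 1] * sigmas[:, 1, 0]
        self.draws_ = np.pi * np.sqrt(dets)
        self.sea_b_ = float(self.draws_.mean())
        lo, hi = np.quantile(self.draws_, [0.025, 0.975])
        self.credible_interval_ = (float(lo), float(hi))
        self.n_samples_ = n
        return self


@dataclass
class PosteriorNiche:
    """Named posterior draws of one species' niche area."""

    species: str
    draws: np.ndarray
    sea_b: float
    credible_interval: tuple[float, float]

    @classmethod
    def from_estimator(cls, species: str, est: BayesianNiche) -> "PosteriorNiche":
        return cls(species=species, draws=est.draws_, sea_b=est.sea_b_,
                   credible_interval=est.credible_interval_)


def sample_posterior(points, draws: int = 10_000, seed=None, species: str = "sample",
                     **prior_kwargs) -> PosteriorNiche:
    """Draw the niche-area posterior for one species' point cloud."""
    est = BayesianNiche(n_draws=draws, random_state=seed, **prior_kwargs).fit(points)
    name = getattr(points, "species", species)
    return PosteriorNiche.from_estimator(name, est)


def prob_smaller(a: PosteriorNiche, b: PosteriorNiche) -> float:
    """P(niche of ``a`` < niche of ``b``): fraction of index-paired draws with a < b."""
    if len(a.draws) != len(b.draws):
        raise ValueError("posteriors must have equal draw counts for index pairing")
    return float(np.mean(a.draws < b.draws))


def probability_matrix(posteriors: list[PosteriorNiche]) -> pd.DataFrame:
    """Pairwise niche-size probability matrix.

    Entry (row i, column j) is the probability that species i's niche is
    smaller than species j's (so columns read as "larger than").  The
    diagonal is NaN.  Off-diagonal pairs sum to 1 up to tie mass.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least 2 species")
    labels = [p.species for p in posteriors]
    m = np.full((len(labels), len(labels)), np.nan)
    for i, a in enumerate(posteriors):
        for j, b in enumerate(posteriors):
            if i != j:
                m[i, j] = prob_smaller(a, b)
    return pd.DataFrame(m, index=labels, columns=labels)
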