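"""Layman population-level trophic-diversity metrics and their bootstrap.

Four descriptors of a species' (δ13C, δ15N) point cloud:

* Hull  — convex-hull area (‰²), the total occupied isotopic space;
* CD    — mean Euclidean distance to the centroid (‰), overall dispersion;
* MNND  — mean nearest-neighbour distance (‰), point packing;
* SDNND — population SD of those nearest-neighbour distances (‰), evenness.

Hull and CD grow with sample size, so cross-species comparisons resample each
species to a common fixed n (default 50, just under the smallest field sample)
and average the metric over R replicates (default 1005); subscript "b" marks
those bootstrap means.  Resampling is with replacement by default, with a
without-replacement (rarefaction) switch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .ellipse import _as_xy


@dataclass
class LaymanMetrics:
    hull: float   # ‰²
    cd: float     # ‰
    mnnd: float   # ‰
    sdnnd: float  # ‰

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class BootstrappedMetrics:
    base: LaymanMetrics       # metrics on the full sample
    means: LaymanMetrics      # metric means over R resamples of size n
    R: int
    n: int
    seed: int | None
    with_replacement: bool


def layman_metrics(points) -> LaymanMetrics:
    """Compute the four Layman metrics for one point cloud (n ≥ 2).

    The hull is 0 for fewer than 3 distinct non-collinear points; duplicate
    points contribute zero nearest-neighbour distances (no jittering); SDNND
    uses the population (divisor N) standard deviation.
    """
    X = _as_xy(points)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"Layman metrics require n >= 2 points, got {n}")
    try:
        hull = float(ConvexHull(X).volume)  # 2-D "volume" is the polygon area
    except QhullError:
        hull = 0.0  # collinear or duplicate-degenerate cloud
    centroid = X.mean(axis=0)
    cd = float(np.mean(np.linalg.norm(X - centroid, axis=1)))
    d = squareform(pdist(X))
    np.fill_diagonal(d, np.inf)
    nnd = d.min(axis=1)
    return LaymanMetrics(hull=hull, cd=cd, mnnd=float(nnd.mean()),
                         sdnnd=float(nnd.std(ddof=0)))


def bootstrap_metrics(points, n: int = 50, R: int = 1005, seed=None,
                      with_replacement: bool = True) -> BootstrappedMetrics:
    """Average the Layman metrics over R resamples of fixed size n."""
    X = _as_xy(points)
    N = X.shape[0]
    if R < 1:
        raise ValueError("R must be >= 1")
    if n < 2:
        raise ValueError("resample size n must be >= 2")
    if not with_replacement and n > N:
        raise ValueError(f"cannot draw {n} of {N} points without replacement")
    rng = np.random.default_rng(seed)
    acc = np.zeros(4)
    for _ in range(R):
        idx = rng.choice(N, size=n, replace=with_replacement)
        m = layman_metrics(X[idx])
        acc += (m.hull, m.cd, m.mnnd, m.sdnnd)
    acc /= R
    return BootstrappedMetrics(
        base=layman_metrics(X),
        means=LaymanMetrics(*acc),
        R=R, n=n, seed=seed, with_replacement=with_replacement,
    )


def metric_size_dependence(values, sample_sizes) -> tuple[float, float, int]:
    """OLS of a per-species metric on sample size: returns (r², two-sided p, slope sign).

    Used to verify that raw Hull/CD track n across species while the
    bootstrapped variants do not.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(sample_sizes, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue), int(np.sign(res.slope))
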