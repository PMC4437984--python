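import numpy as np
import pytest

from isoniche import (
    OverlapResult,
    aggregate_containment,
    as_dataset,
    ellipse_overlap,
    fit_standard_ellipse,
    median_overlap,
    monte_carlo_overlap,
    pairwise_overlaps,
)


def _circle_points(radius, center=(0.0, 0.0), n=400, seed=0):
    """Point cloud whose fitted SEAc ellipse is (almost exactly) a circle of
    the requested radius: sample-cov-whitened normal scaled by radius·√(n−2)/(n−1)... """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    X -= X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T  # exact identity sample cov
    # SEAc = π r²: shrink so the (n−1)/(n−2) correction lands on radius exactly
    X *= radius * np.sqrt((n - 2) / (n - 1))
    return X + np.asarray(center)


def test_identical_ellipses_overlap_100():
    e = fit_standard_ellipse(_circle_points(1.5))
    r = ellipse_overlap(e, e)
    assert r.pct_of_a == pytest.approx(100.0, abs=0.1)
    assert r.pct_of_b == pytest.approx(100.0, abs=0.1)


def test_distant_ellipses_are_disjoint():
    a = fit_standard_ellipse(_circle_points(1.0))
    b = fit_standard_ellipse(_circle_points(1.0, center=(1e6, 0.0), seed=1))
    r = ellipse_overlap(a, b)
    assert r.intersection_area == 0.0
    assert r.pct_of_a == r.pct_of_b == 0.0


def test_concentric_circles_closed_form():
    # circles r=1 and r=2: intersection π, covers 25% of the larger
    a = fit_standard_ellipse(_circle_points(1.0))
    b = fit_standard_ellipse(_circle_points(2.0, seed=1))
    r = ellipse_overlap(a, b)
    assert r.intersection_area == pytest.approx(np.pi, rel=2e-3)
    assert r.pct_of_a == pytest.approx(100.0, abs=0.1)
    assert r.pct_of_b == pytest.approx(25.0, abs=0.1)


def test_intersection_symmetric_and_bounded(small_community):
    _, _, datasets = small_community
    ells = {d.species: fit_standard_ellipse(d) for d in datasets}
    for r in pairwise_overlaps(ells):
        swapped = ellipse_overlap(ells[r.species_b], ells[r.species_a])
        assert r.intersection_area == pytest.approx(swapped.intersection_area, rel=1e-9)
        assert 0 <= r.intersection_area <= min(ells[r.species_a].seac_, ells[r.species_b].seac_) + 1e-9
        assert 0 <= r.pct_of_a <= 100 and 0 <= r.pct_of_b <= 100


def test_discretization_converges():
    rng = np.random.default_rng(11)
    a = fit_standard_ellipse(rng.multivariate_normal([0, 0], [[2, 0.6], [0.6, 1]], 100))
    b = fit_standard_ellipse(rng.multivariate_normal([1, 0.5], [[1, -0.2], [-0.2, 1.5]], 100))
    r256 = ellipse_overlap(a, b, vertices=256)
    r4096 = ellipse_overlap(a, b, vertices=4096)
    assert abs(r256.pct_of_a - r4096.pct_of_a) < 0.2
    assert abs(r256.pct_of_b - r4096.pct_of_b) < 0.2
    with pytest.raises(ValueError):
        ellipse_overlap(a, b, vertices=32)


def test_polygon_agrees_with_monte_carlo_grid_oracle():
    rng = np.random.default_rng(13)
    for trial in range(3):
        a = fit_standard_ellipse(rng.multivariate_normal([0, 0], [[2, 0.6], [0.6, 1]], 150))
        b = fit_standard_ellipse(rng.multivariate_normal(rng.uniform(-1, 1, 2),
                                                         [[1, -0.3], [-0.3, 2]], 150))
        clip = ellipse_overlap(a, b).intersection_area
        mc = monte_carlo_overlap(a, b, n_points=1_000_000, seed=trial)
        # compare as percent of the smaller ellipse
        denom = min(a.seac_, b.seac_)
        assert abs(clip - mc) / denom * 100 < 0.5


class TestMedianOverlap:
    def _results(self, pcts):
        return [OverlapResult("focal", f"p{i}", 1.0 if p > 0 else 0.0, p, p)
                for i, p in enumerate(pcts)]

    def test_median_includes_zero_pairs(self):
        med, partners = median_overlap(self._results([0, 0, 0, 10, 20, 30]), "focal")
        assert med == 5.0  # hand median of {0,0,0,10,20,30}
        assert partners == 3

    def test_disjoint_and_identical_extremes(self):
        assert median_overlap(self._results([0, 0, 0]), "focal")[0] == 0.0
        assert median_overlap(self._results([100, 100]), "focal")[0] == 100.0

    def test_exclude_zeros_switch_and_unknown_focal(self):
        med, _ = median_overlap(self._results([0, 0, 10, 30]), "focal", include_zeros=False)
        assert med == 20.0
        with pytest.raises(KeyError):
            median_overlap(self._results([1.0]), "nobody")


class TestAggregateContainment:
    def test_focal_inside_aggregate(self):
        # focal is a small circle at the centre of two big flanking species
        community = [
            as_dataset(_circle_points(0.5), species="focal"),
            as_dataset(_circle_points(6.0, center=(-1, 0), seed=2), species="left"),
            as_dataset(_circle_points(6.0, center=(1, 0), seed=3), species="right"),
        ]
        agg = aggregate_containment(community, "focal")
        assert agg.containment_pct == pytest.approx(100.0, abs=0.1)

    def test_focal_far_outside(self):
        community = [
            as_dataset(_circle_points(0.5, center=(500, 500)), species="focal"),
            as_dataset(_circle_points(2.0, seed=2), species="left"),
            as_dataset(_circle_points(2.0, center=(1, 0), seed=3), species="right"),
        ]
        assert aggregate_containment(community, "focal").containment_pct == 0.0

    def test_half_covered_by_construction(self):
        # aggregate ≈ a huge half-plane-like ellipse centred far left whose
        # boundary passes through the focal centre; brute-force grid oracle
        focal_pts = _circle_points(1.0)
        focal = fit_standard_ellipse(focal_pts)
        big = 60.0
        community = [
            as_dataset(focal_pts, species="focal"),
            as_dataset(_circle_points(big, center=(-big, 3), seed=4), species="l1"),
            as_dataset(_circle_points(big, center=(-big, -3), seed=5), species="l2"),
        ]
        agg = aggregate_containment(community, "focal")
        # independent grid oracle over the focal bounding box
        rng = np.random.default_rng(6)
        pts = rng.uniform(-1.2, 1.2, size=(200_000, 2))
        agg_ell = agg.ellipse
        sf = np.sqrt(focal.seac_ / focal.sea_)
        sa = np.sqrt(agg_ell.seac_ / agg_ell.sea_)
        in_f = focal.mahalanobis_sq(pts) <= sf ** 2
        in_a = agg_ell.mahalanobis_sq(pts) <= sa ** 2
        oracle = 100.0 * np.sum(in_f & in_a) / np.sum(in_f)
        assert agg.containment_pct == pytest.approx(oracle, abs=1.0)
        assert 20 < agg.containment_pct < 80  # genuinely partial coverage

    def test_unknown_species_raises(self, small_community):
        _, _, datasets = small_community
        with pytest.raises(KeyError):
            aggregate_containment(datasets, "missing")
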