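import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoniche import DegenerateDataError, StandardEllipse, fit_standard_ellipse
from isoniche.ellipse import community_ellipses, pooled_moments
from isoniche.io import as_dataset


def _points_with_identity_cov(n=10, seed=0):
    """n points whose *sample* covariance is exactly the identity."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    X -= X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    L = np.linalg.cholesky(cov)
    return X @ np.linalg.inv(L).T


class TestClosedForms:
    def test_identity_sample_covariance_gives_sea_pi(self):
        X = _points_with_identity_cov(n=10)
        e = fit_standard_ellipse(X)
        assert e.sea_ == pytest.approx(np.pi, abs=1e-9)
        assert e.seac_ == pytest.approx(np.pi * 9 / 8, abs=1e-9)
        assert e.eccentricity_ == pytest.approx(0.0, abs=1e-6)

    def test_cross_of_four_points(self):
        # hand-computed: sample covariance diag(2/3, 2/3)
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        e = fit_standard_ellipse(X)
        assert np.allclose(e.covariance_, np.eye(2) * 2 / 3)
        assert e.sea_ == pytest.approx(2 * np.pi / 3, abs=1e-12)
        assert e.seac_ == pytest.approx(np.pi, abs=1e-12)  # ×(n−1)/(n−2) = 3/2

    @pytest.mark.parametrize("lam,expected", [
        ((4.0, 1.0), np.sqrt(3) / 2),   # semi-axes (2, 1)
        ((9.0, 1.0), np.sqrt(1 - 1 / 9)),
        ((5.0, 5.0), 0.0),
    ])
    def test_eccentricity_closed_forms(self, lam, expected):
        X = _points_with_identity_cov(n=50) * np.sqrt(lam)
        e = fit_standard_ellipse(X)
        # √(1 − λ2/λ1) amplifies machine-precision eigenvalue gaps to ~1e-8
        assert e.eccentricity_ == pytest.approx(expected, abs=1e-6)
        assert e.sea_ == pytest.approx(np.pi * np.sqrt(lam[0] * lam[1]), abs=1e-9)


class TestErrors:
    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateDataError):
            fit_standard_ellipse(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateDataError):
            fit_standard_ellipse(np.array([[0.0, 0.0], [1.0, 0.5]]))


class TestInvariance:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(angle=st.floats(0, np.pi), dx=st.floats(-50, 50), dy=st.floats(-50, 50),
           seed=st.integers(0, 100))
    def test_sea_invariant_under_rotation_translation(self, angle, dx, dy, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 2)) @ np.array([[2.0, 0.4], [0.4, 0.7]])
        c, s = np.cos(angle), np.sin(angle)
        Y = X @ np.array([[c, -s], [s, c]]).T + [dx, dy]
        a, b = fit_standard_ellipse(X), fit_standard_ellipse(Y)
        assert b.sea_ == pytest.approx(a.sea_, rel=1e-9)
        assert b.eccentricity_ == pytest.approx(a.eccentricity_, rel=1e-7)

    def test_seac_ratio_exact_and_vanishing(self):
        for n in (3, 10, 1000):
            X = np.random.default_rng(n).normal(size=(n, 2))
            e = fit_standard_ellipse(X)
            assert e.seac_ / e.sea_ == pytest.approx((n - 1) / (n - 2), rel=1e-12)
            assert e.seac_ > e.sea_

    def test_eccentricity_scale_invariant(self):
        X = np.random.default_rng(1).normal(size=(40, 2)) * [3.0, 1.0]
        e1, e2 = fit_standard_ellipse(X), fit_standard_ellipse(X * 7.5)
        assert e2.eccentricity_ == pytest.approx(e1.eccentricity_, rel=1e-12)


class TestContainment:
    def test_fraction_within_on_self_draws_near_39_percent(self):
        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        X = rng.multivariate_normal([5.0, -3.0], cov, size=100_000)
        e = fit_standard_ellipse(X)
        frac = e.fraction_within(X)
        # 1 − e^(−1/2) ≈ 0.3935: the "core" ~40% niche
        assert 0.385 <= frac <= 0.402

    def test_degenerate_point_positions(self):
        X = np.random.default_rng(3).normal(size=(50, 2))
        e = fit_standard_ellipse(X)
        assert e.fraction_within(np.tile(e.location_, (5, 1))) == 1.0
        far = e.location_ + 1e6
        assert e.fraction_within(np.tile(far, (5, 1))) == 0.0


class TestStandardization:
    def test_pooled_standardization_changes_shape_not_validity(self, small_community):
        _, _, datasets = small_community
        raw = community_ellipses(datasets)
        std = community_ellipses(datasets, standardize="pooled")
        for sp in raw:
            assert 0 <= std[sp].eccentricity_ < 1
            assert std[sp].sea_ > 0
        center, scale = pooled_moments(datasets)
        assert np.all(scale > 0)

    def test_species_standardization_makes_axes_unit_variance(self):
        X = np.random.default_rng(0).normal(size=(100, 2)) * [4.0, 0.5]
        e = StandardEllipse(standardize=True).fit(X)
        assert np.allclose(np.diag(e.covariance_), 1.0, atol=1e-12)

    def test_rotation_angle_convention(self):
        X = np.random.default_rng(2).normal(size=(500, 2)) * [5.0, 1.0]
        e = fit_standard_ellipse(X)
        assert -np.pi / 2 < e.rotation_ <= np.pi / 2
        assert abs(e.rotation_) < 0.15  # major axis ≈ along x

    def test_sklearn_params_roundtrip(self):
        e = StandardEllipse(standardize=True)
        assert e.get_params()["standardize"] is True
        e.set_params(standardize=False)
        assert e.standardize is False


def test_boundary_polygon_area_matches_seac():
    X = np.random.default_rng(5).normal(size=(60, 2)) @ np.array([[1.5, 0.3], [0.3, 0.6]])
    e = fit_standard_ellipse(X)
    poly = e.boundary(vertices=256, scale="seac")
    x, y = poly[:, 0], poly[:, 1]
    shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    assert shoelace == pytest.approx(e.seac_, rel=1e-12)


def test_dataset_input_equivalent_to_array(small_community):
    _, _, datasets = small_community
    d = datasets[0]
    assert fit_standard_ellipse(d).sea_ == fit_standard_ellipse(d.xy).sea_
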