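"""Layman metrics, standard ellipses, SEAb sampler and ellipse overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoniche.niche_metrics import (
    DegenerateGroupError,
    EllipseFit,
    IsotopePoints,
    SEAbConfig,
    ellipse_overlap,
    fit_standard_ellipse,
    layman_metrics,
    sample_seab,
)
from isoniche.sample_io import ValidationError

from oracles import ellipse_polygon, hull_area_bruteforce, nnd_bruteforce


def pts(array, label="g"):
    return IsotopePoints(label, np.asarray(array, dtype=float))


class TestLaymanMetrics:
    def test_unit_square(self):
        m = layman_metrics(pts([(0, 0), (1, 0), (0, 1), (1, 1)]))
        assert m.dC_range == m.dN_range == 1.0
        assert m.TA == pytest.approx(1.0)
        assert m.CD == pytest.approx(math.sqrt(0.5))
        assert m.NND == pytest.approx(1.0)
        assert m.SDNND == pytest.approx(0.0)

    def test_right_triangle_area(self):
        assert layman_metrics(pts([(0, 0), (2, 0), (0, 2)])).TA == pytest.approx(2.0)

    def test_collinear_points_have_zero_hull_area(self):
        assert layman_metrics(pts([(0, 0), (1, 1), (2, 2), (3, 3)])).TA == 0.0

    def test_duplicate_points_give_zero_nnd(self):
        # nearest neighbours: 0 for the coincident pair, 5√2 for the third
        m = layman_metrics(pts([(0, 0), (0, 0), (5, 5)]))
        assert m.NND == pytest.approx(5 * math.sqrt(2) / 3, rel=1e-12)

    def test_small_n_markers(self):
        one = layman_metrics(pts([(1, 2)]))
        assert one.TA is None and one.NND is None and one.SDNND is None
        two = layman_metrics(pts([(0, 0), (1, 0)]))
        assert two.TA is None and two.NND == pytest.approx(1.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValidationError):
            pts(np.empty((0, 2)))

    def test_hull_area_matches_bruteforce_oracle(self, rng):
        """qhull TA equals gift-wrapping + shoelace for many tiny clouds."""
        for n in range(3, 9):
            for _ in range(40):
                cloud = rng.uniform(-5, 5, size=(n, 2))
                ta = layman_metrics(pts(cloud)).TA
                assert ta == pytest.approx(hull_area_bruteforce(cloud), rel=1e-9, abs=1e-12)

    def test_nnd_matches_quadratic_scan(self, rng):
        for n in (2, 5, 50, 200):
            cloud = rng.normal(size=(n, 2))
            m = layman_metrics(pts(cloud))
            mean, sd = nnd_bruteforce(cloud)
            assert m.NND == pytest.approx(mean, rel=1e-12)
            assert m.SDNND == pytest.approx(sd, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 1000),
    )
    def test_translation_and_scaling_laws(self, dx, dy, scale, seed):
        """Translation leaves every metric fixed; uniform scaling moves
        areas quadratically and distances linearly."""
        cloud = np.random.default_rng(seed).normal(size=(7, 2))
        base = layman_metrics(pts(cloud))
        shifted = layman_metrics(pts(cloud + [dx, dy]))
        assert shifted.TA == pytest.approx(base.TA, rel=1e-8, abs=1e-9)
        assert shifted.CD == pytest.approx(base.CD, rel=1e-8, abs=1e-9)
        assert shifted.NND == pytest.approx(base.NND, rel=1e-8, abs=1e-9)
        scaled = layman_metrics(pts(cloud * scale))
        assert scaled.TA == pytest.approx(base.TA * scale**2, rel=1e-8)
        assert scaled.CD == pytest.approx(base.CD * scale, rel=1e-8)
        assert scaled.NND == pytest.approx(base.NND * scale, rel=1e-8)


class TestStandardEllipse:
    def test_plus_pattern_closed_form(self):
        # covariance diag(0.5, 0.5): SEA = π/2, SEAc = SEA·4/3
        fit = fit_standard_ellipse(pts([(1, 0), (-1, 0), (0, 1), (0, -1), (0, 0)]))
        assert np.allclose(fit.covariance, np.diag([0.5, 0.5]))
        assert fit.SEA == pytest.approx(math.pi / 2)
        assert fit.SEAc == pytest.approx(math.pi / 2 * 4 / 3)

    def test_translation_invariance(self, rng):
        cloud = rng.normal(size=(20, 2))
        a = fit_standard_ellipse(pts(cloud))
        b = fit_standard_ellipse(pts(cloud + [100.0, -50.0]))
        assert b.SEA == pytest.approx(a.SEA, rel=1e-10)
        assert b.SEAc == pytest.approx(a.SEAc, rel=1e-10)

    def test_seac_exceeds_sea(self, rng):
        for n in (3, 5, 30):
            fit = fit_standard_ellipse(pts(rng.normal(size=(n, 2))))
            assert fit.SEAc > fit.SEA
            assert fit.SEAc == pytest.approx(fit.SEA * (n - 1) / (n - 2))

    def test_sea_equals_pi_sqrt_det(self, rng):
        fit = fit_standard_ellipse(pts(rng.normal(size=(50, 2)) @ [[2, 0.5], [0, 1]]))
        assert fit.SEA == pytest.approx(math.pi * math.sqrt(np.linalg.det(fit.covariance)))
        assert fit.eigenvalues[0] >= fit.eigenvalues[1] > 0

    def test_too_small_and_collinear_groups_error(self):
        with pytest.raises(DegenerateGroupError, match="too small"):
            fit_standard_ellipse(pts([(0, 0), (1, 1)]))
        with pytest.raises(DegenerateGroupError, match="degenerate|collinear"):
            fit_standard_ellipse(pts([(0, 0), (1, 1), (2, 2), (3, 3)]))

    def test_closed_form_recovery_at_large_n(self):
        """SEAc -> π√det(Σ) for synthetic normals with known covariance."""
        sigma = np.array([[1.4**2, 0.0], [0.0, 1.7**2]])
        rng = np.random.default_rng(11)
        cloud = rng.multivariate_normal([0, 0], sigma, size=1000)
        fit = fit_standard_ellipse(pts(cloud))
        truth = math.pi * math.sqrt(np.linalg.det(sigma))
        assert abs(fit.SEAc - truth) / truth < 0.10


def scaled_config(iterations=4000, chains=1, burn_in=500, thinning=5):
    return SEAbConfig(iterations=iterations, chains=chains, burn_in=burn_in, thinning=thinning)


class TestSEAb:
    def test_draw_count_matches_config(self, rng):
        cfg = SEAbConfig(iterations=2000, chains=3, burn_in=200, thinning=10)
        post = sample_seab(pts(rng.normal(size=(30, 2))), cfg, seed=1)
        assert post.n_draws == 3 * (2000 - 200) // 10
        assert np.all(post.draws > 0)

    def test_posterior_mean_near_pi_for_unit_covariance(self):
        rng = np.random.default_rng(0)
        cloud = rng.standard_normal((300, 2))
        post = sample_seab(pts(cloud), scaled_config(), seed=7)
        assert abs(post.mean - math.pi) / math.pi < 0.05

    def test_same_seed_same_draws(self, rng):
        cloud = rng.normal(size=(25, 2))
        a = sample_seab(pts(cloud), scaled_config(iterations=1000, burn_in=100), seed=42)
        b = sample_seab(pts(cloud), scaled_config(iterations=1000, burn_in=100), seed=42)
        assert np.array_equal(a.draws, b.draws)
        c = sample_seab(pts(cloud), scaled_config(iterations=1000, burn_in=100), seed=43)
        assert not np.array_equal(a.draws, c.draws)

    def test_posterior_mean_approaches_seac_with_n(self):
        rng = np.random.default_rng(5)
        sigma = np.array([[2.0, 0.6], [0.6, 1.0]])
        rel = {}
        for n in (30, 1000):
            cloud = rng.multivariate_normal([0, 0], sigma, size=n)
            p = pts(cloud)
            fit = fit_standard_ellipse(p)
            post = sample_seab(p, scaled_config(), seed=n)
            rel[n] = abs(post.mean - fit.SEAc) / fit.SEAc
        assert rel[1000] < rel[30]
        assert rel[1000] < 0.02

    def test_degenerate_data_error_before_sampling(self):
        with pytest.raises(DegenerateGroupError):
            sample_seab(pts([(0, 0), (1, 1), (2, 2)]), scaled_config(), seed=0)

    def test_summaries_nested_intervals(self, rng):
        post = sample_seab(pts(rng.normal(size=(40, 2))), scaled_config(), seed=9)
        s = post.summaries()
        assert s["ci95_lo"] <= s["ci75_lo"] <= s["ci50_lo"]
        assert s["ci50_hi"] <= s["ci75_hi"] <= s["ci95_hi"]
        assert s["ci95_lo"] <= s["mean"] <= s["ci95_hi"]


def make_fit(centroid, cov, n=100, label="f"):
    cov = np.asarray(cov, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    sea = math.pi * math.sqrt(eigvals[0] * eigvals[1])
    return EllipseFit(
        label, np.asarray(centroid, dtype=float), cov,
        eigvals[order], eigvecs[:, order], sea, sea * (n - 1) / (n - 2), n,
    )


def shapely_intersection_area(fitA, fitB, r2A, r2B):
    from shapely.geometry import Polygon

    pa = Polygon(ellipse_polygon(fitA.centroid, fitA.covariance, r2A))
    pb = Polygon(ellipse_polygon(fitB.centroid, fitB.covariance, r2B))
    return pa.intersection(pb).area


class TestEllipseOverlap:
    def test_identical_ellipses_full_overlap(self):
        f = make_fit([0, 0], [[2.0, 0.3], [0.3, 1.0]])
        res = ellipse_overlap(f, f)
        assert res.prop_of_B == pytest.approx(100.0)
        assert res.area_intersection == pytest.approx(res.area_B, rel=1e-3)

    def test_distant_centroids_zero_overlap(self):
        a = make_fit([0, 0], np.eye(2))
        b = make_fit([100, 0], np.eye(2))
        res = ellipse_overlap(a, b)
        assert res.area_intersection == 0.0 and res.prop_of_B == 0.0

    def test_concentric_four_fold_covariance_is_quarter(self):
        """B's covariance = 4·A's: A's ellipse sits inside B's, whose area
        is 4× larger, so A occupies exactly 25% of B."""
        cov = np.array([[1.5, 0.4], [0.4, 0.8]])
        a = make_fit([0, 0], cov, n=50)
        b = make_fit([0, 0], 4 * cov, n=50)
        res = ellipse_overlap(a, b, resolution=1e-3)
        assert res.prop_of_B == pytest.approx(25.0, rel=2.5e-3)

    def test_grid_matches_polygon_clipping_oracle(self):
        """Partial overlap agrees with an independent shapely computation."""
        a = make_fit([0, 0], [[2.0, 0.5], [0.5, 1.0]], n=40)
        b = make_fit([1.2, 0.4], [[1.0, -0.2], [-0.2, 1.5]], n=25)
        res = ellipse_overlap(a, b, resolution=1e-4)
        r2A = (a.n - 1) / (a.n - 2)
        r2B = (b.n - 1) / (b.n - 2)
        oracle = shapely_intersection_area(a, b, r2A, r2B)
        assert res.area_intersection == pytest.approx(oracle, rel=2e-3)
        assert res.area_A == pytest.approx(math.pi * math.sqrt(np.linalg.det(a.covariance)) * r2A)

    def test_intersection_symmetric(self):
        a = make_fit([0, 0], [[2.0, 0.5], [0.5, 1.0]], n=40)
        b = make_fit([0.8, 0.2], [[1.0, 0.0], [0.0, 1.5]], n=25)
        ab = ellipse_overlap(a, b, resolution=1e-4)
        ba = ellipse_overlap(b, a, resolution=1e-4)
        assert ab.area_intersection == pytest.approx(ba.area_intersection, rel=1e-3)
        assert ab.prop_of_B != pytest.approx(ba.prop_of_B)  # denominators differ

    def test_default_matches_seac_area(self):
        f = make_fit([0, 0], np.eye(2), n=10)
        res = ellipse_overlap(f, f)
        assert res.area_A == pytest.approx(f.SEAc, rel=1e-12)

    def test_explicit_coverage(self):
        f = make_fit([0, 0], np.eye(2), n=10)
        res = ellipse_overlap(f, f, coverage=0.95)
        # 95% contour of a unit normal: area = π·χ²₂(0.95)
        assert res.area_A == pytest.approx(math.pi * 5.991, rel=1e-3)

    def test_invalid_coverage_rejected(self):
        f = make_fit([0, 0], np.eye(2))
        with pytest.raises(ValidationError):
            ellipse_overlap(f, f, coverage=1.5)
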