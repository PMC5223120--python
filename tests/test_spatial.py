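"""G-function, CSR envelopes, DCLF test, characteristic distances, summaries."""

import numpy as np
import pytest

from myrmeco.spatial import (
    DiscRegion,
    PointPattern,
    PolygonRegion,
    area_of_interest,
    characteristic_distances,
    dclf_test,
    distance_summary,
    envelope,
    g_function,
    nn_distances,
    radial_density,
    simulate_csr,
    simulate_thomas,
)

REG = DiscRegion(radius=195.0)


def _pattern(points, region=None):
    return PointPattern(np.asarray(points, dtype=float), region or REG)


class TestAreaOfInterest:
    def test_five_cm_buffer_on_two_metre_arena(self):
        aoi = area_of_interest(DiscRegion(radius=200.0), 5.0)
        assert aoi.radius == 195.0

    def test_zero_buffer_unchanged(self):
        aoi = area_of_interest(DiscRegion(radius=200.0), 0.0)
        assert aoi.radius == 200.0

    def test_buffer_equal_radius_raises(self):
        with pytest.raises(ValueError):
            area_of_interest(DiscRegion(radius=5.0), 5.0)


class TestNNDistances:
    def test_pair_five_cm_apart(self):
        d = nn_distances(_pattern([(0, 0), (5, 0)]))
        np.testing.assert_allclose(d, [5, 5])

    def test_collinear_points(self):
        d = nn_distances(_pattern([(0, 0), (1, 0), (3, 0)]))
        np.testing.assert_allclose(d, [1, 1, 2])

    def test_duplicates_give_zero(self):
        d = nn_distances(_pattern([(1, 1), (1, 1), (7, 7)]))
        assert d.min() == 0.0

    def test_single_point_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            nn_distances(_pattern([(0, 0)]))


class TestGFunction:
    def test_step_at_pair_distance(self):
        g = g_function(_pattern([(0, 0), (5, 0)]), d_grid=np.array([4.9, 5.0]))
        np.testing.assert_allclose(g.values, [0.0, 1.0])

    def test_is_valid_cdf(self, rng):
        for _ in range(5):
            pat = simulate_csr(40, REG, rng)
            g = g_function(pat)
            assert (np.diff(g.values) >= 0).all()
            assert g.values.min() >= 0 and g.values.max() <= 1
            assert g.values[-1] == 1.0  # grid covers the region diameter

    def test_matches_poisson_closed_form(self):
        rng = np.random.default_rng(0)
        n = 10_000
        big = DiscRegion(radius=100.0)
        pat = simulate_csr(n, big, rng)
        rho = n / big.area
        d = np.linspace(0, 5, 200)
        g = g_function(pat, d_grid=d)
        theo = 1 - np.exp(-rho * np.pi * d**2)
        assert np.abs(g.values - theo).max() <= 0.02


class TestSimulateCSR:
    def test_zero_points(self):
        pat = simulate_csr(0, REG, 0)
        assert pat.n == 0

    def test_all_points_inside_region(self, rng):
        pat = simulate_csr(500, REG, rng)
        assert REG.contains(pat.points).all()

    def test_mean_nn_distance_matches_csr_expectation(self):
        rng = np.random.default_rng(1)
        n = 1000
        means = [nn_distances(simulate_csr(n, REG, rng)).mean() for _ in range(30)]
        expected = 1.0 / (2.0 * np.sqrt(n / REG.area))
        assert abs(np.mean(means) - expected) / expected < 0.03

    def test_polygon_region_sampling(self, rng):
        poly = PolygonRegion(np.array([[0, 0], [10, 0], [10, 10], [0, 10]]))
        pat = simulate_csr(200, poly, rng)
        assert pat.n == 200
        assert poly.contains(pat.points).all()


class TestEnvelope:
    def test_bounds_ordered(self, rng):
        pat = simulate_csr(50, REG, rng)
        env = envelope(pat, n_sim=20, rng=rng)
        assert (env.lo <= env.sim_mean.values + 1e-12).all()
        assert (env.sim_mean.values <= env.hi + 1e-12).all()

    def test_single_simulation_degenerate_band(self, rng):
        pat = simulate_csr(30, REG, rng)
        env = envelope(pat, n_sim=1, rng=rng)
        np.testing.assert_array_equal(env.lo, env.hi)
        np.testing.assert_array_equal(env.lo, env.sim_curves[0])

    def test_pointwise_exceedance_rare_under_csr(self):
        # a rank-1 envelope of 99 sims is exceeded at a FIXED grid point
        # with probability ~2/100; check a generous bound over 60 trials
        rng = np.random.default_rng(5)
        bad = total = 0
        for _ in range(60):
            pat = simulate_csr(100, REG, rng)
            env = envelope(pat, n_sim=99, rng=rng)
            for idx in (50, 100, 200):
                total += 1
                v = env.observed.values[idx]
                bad += not (env.lo[idx] <= v <= env.hi[idx])
        assert bad / total <= 0.06


class TestDCLF:
    def test_observed_equal_to_mean_gives_zero_u(self, rng):
        pat = simulate_csr(50, REG, rng)
        env = envelope(pat, n_sim=50, rng=rng)
        env.observed.values[:] = env.sim_mean.values
        res = dclf_test(env)
        assert res.u_obs == 0.0
        assert res.p > 0.5
        assert res.verdict == "CSR"

    def test_d_max_outside_grid_raises(self, rng):
        pat = simulate_csr(20, REG, rng)
        env = envelope(pat, n_sim=5, rng=rng)
        with pytest.raises(ValueError):
            dclf_test(env, d_max=1e9)

    def test_rank_one_in_1000_simulations_is_p_one_over_1001(self):
        # an extreme clustered pattern against 1000 CSR simulations
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=1.5, size=(30, 2))
        pat = _pattern(pts)
        env = envelope(pat, n_sim=1000, rng=rng)
        res = dclf_test(env)
        assert res.rank == 1
        assert res.p == pytest.approx(1.0 / 1001.0)
        assert f"{res.p:.3f}" == "0.001"
        assert res.verdict == "clustered"

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(400):
            pat = simulate_csr(50, REG, rng)
            env = envelope(pat, n_sim=99, rng=rng)
            rejections += dclf_test(env).verdict == "clustered"
        assert 0.03 <= rejections / 400 <= 0.08

    def test_power_on_thomas_clusters(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            pat = simulate_thomas(20, 10, 3.0, REG, rng)
            env = envelope(pat, n_sim=99, rng=rng)
            hits += dclf_test(env).verdict == "clustered"
        assert hits / 100 >= 0.95


class TestCharacteristicDistances:
    def test_not_clustered_gives_empty(self, rng):
        pat = simulate_csr(50, REG, rng)
        env = envelope(pat, n_sim=99, rng=np.random.default_rng(0))
        res = dclf_test(env)
        if res.verdict == "CSR":  # overwhelmingly likely with this seed
            cd = characteristic_distances(env, res)
            assert cd.f_star == 0.0
            assert cd.nndist_cluster is None

    def test_two_tight_clusters(self):
        rng = np.random.default_rng(3)
        c1 = np.array([40.0, 0.0]) + rng.uniform(-1, 1, (5, 2))
        c2 = np.array([-40.0, 30.0]) + rng.uniform(-1, 1, (5, 2))
        pat = _pattern(np.vstack([c1, c2]))
        env = envelope(pat, n_sim=199, rng=rng)
        res = dclf_test(env)
        assert res.verdict == "clustered"
        cd = characteristic_distances(env, res)
        assert cd.f_star > 0
        assert cd.nndist_cluster[0] <= 2.0
        assert cd.nndist_cluster[0] < cd.nndist_csr[0]


class TestRadialDensity:
    def test_all_points_in_first_ring(self):
        pts = [(1.0, 0.0), (0.0, 2.0), (-3.0, 0.0)]
        rings = radial_density(_pattern(pts, DiscRegion(radius=50.0)))
        k, inner, outer, count, density = rings[0]
        assert count == 3
        assert density == pytest.approx(3 / (np.pi * 100))
        assert sum(r[3] for r in rings) == 3

    def test_empty_pattern_zero_densities(self):
        rings = radial_density(_pattern(np.empty((0, 2)), DiscRegion(radius=30.0)))
        assert all(r[4] == 0.0 for r in rings)

    def test_uniform_pattern_flat_profile(self):
        rng = np.random.default_rng(8)
        pat = simulate_csr(20_000, DiscRegion(radius=100.0), rng)
        rings = radial_density(pat)
        densities = [r[4] for r in rings]
        expected = 20_000 / pat.region.area
        assert all(abs(d - expected) / expected < 0.15 for d in densities)

    def test_half_open_ring_convention(self):
        pts = [(10.0, 0.0)]  # exactly on the first ring boundary
        rings = radial_density(_pattern(pts, DiscRegion(radius=50.0)))
        assert rings[0][3] == 0 and rings[1][3] == 1


class TestDistanceSummary:
    def test_median_of_three(self):
        med, q1, q3 = distance_summary(_pattern([(1, 0), (0, 2), (3, 0)]))
        assert med == 2.0

    def test_single_point(self):
        med, q1, q3 = distance_summary(_pattern([(7, 0)]))
        assert med == q1 == q3 == 7.0

    def test_agrees_with_sort_oracle(self, rng):
        pts = rng.uniform(-100, 100, size=(57, 2))
        pat = _pattern(pts)
        med, q1, q3 = distance_summary(pat)
        d = np.sort(np.hypot(pts[:, 0], pts[:, 1]))
        assert med == pytest.approx(np.quantile(d, 0.5))
        assert q1 == pytest.approx(np.quantile(d, 0.25))
        assert q3 == pytest.approx(np.quantile(d, 0.75))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            distance_summary(_pattern(np.empty((0, 2))))
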