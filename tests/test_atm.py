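"""Support regions, the Metropolis-within-Gibbs sampler, and HPD isopleths."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, chisquare, kstest

from azitel.atm import (
    AtmDataError,
    HPDRegion,
    KappaModel,
    MCMCConfig,
    SupportRegion,
    build_support,
    default_radius,
    fit_atm,
    hpd_isopleth,
)
from azitel.circular import expected_bearing, vonmises_sample, wrap_angle


def _obs(rows):
    return pd.DataFrame(rows, columns=["relocation", "station_x", "station_y", "bearing"])


class TestSupportRegion:
    def test_single_circle_area(self):
        s = build_support([(0.0, 0.0)], 100.0)
        assert s.area() == pytest.approx(np.pi * 100.0**2)

    def test_disjoint_circles_area(self):
        s = build_support([(0.0, 0.0), (500.0, 0.0)], 100.0)
        assert s.area() == pytest.approx(2 * np.pi * 100.0**2)

    def test_overlapping_circles_area_vs_mc(self):
        s = build_support([(0.0, 0.0), (120.0, 0.0)], 100.0)
        exact = s.area()
        # Monte Carlo cross-check of the analytic lens formula
        rng = np.random.default_rng(1)
        pts = rng.uniform((-100, -100), (220, 100), size=(400_000, 2))
        mc = np.mean(s.contains(pts)) * 320.0 * 200.0
        assert exact == pytest.approx(mc, rel=0.01)

    def test_sampler_uniform_chisquare(self, rng):
        s = build_support([(0.0, 0.0), (150.0, 0.0), (75.0, 120.0)], 100.0)
        draws = s.sample(100_000, rng)
        assert np.all(s.contains(draws))
        # partition: 40 m squares whose 4 corners all lie inside the union
        # (equal areas -> exactly equal expected counts among those squares)
        x0, y0, x1, y1 = s.bounding_box
        cell = 40.0
        counts = []
        for cx in np.arange(x0, x1 - cell, cell):
            for cy in np.arange(y0, y1 - cell, cell):
                corners = [(cx, cy), (cx + cell, cy), (cx, cy + cell),
                           (cx + cell, cy + cell), (cx + cell / 2, cy + cell / 2)]
                if all(s.contains(np.array(c)) for c in corners):
                    inside = ((draws[:, 0] >= cx) & (draws[:, 0] < cx + cell)
                              & (draws[:, 1] >= cy) & (draws[:, 1] < cy + cell))
                    counts.append(inside.sum())
        assert len(counts) >= 8
        _, p = chisquare(counts)
        assert p > 0.01

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            build_support([(0.0, 0.0)], -1.0)

    def test_default_radius_rule(self):
        stations = np.array([[0.0, 0.0], [100.0, 0.0]])
        assert default_radius(stations) == pytest.approx(300.0)


class TestFitAtm:
    def test_vanishing_noise_recovers_truth(self):
        truth = np.array([50.0, 80.0])
        stations = truth + 300.0 * np.array(
            [[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float
        )
        bearings = [expected_bearing(truth, z) for z in stations]
        obs = _obs([(0, z[0], z[1], b) for z, b in zip(stations, bearings)])
        post = fit_atm(obs, KappaModel(homogeneous=True, mu_beta=np.log(1e6),
                                       sigma2_beta=1e-6),
                       radius_r=400.0, mcmc=MCMCConfig(n_iter=4000, seed=3))
        mean = post.locations[0].mean
        assert np.hypot(mean[0] - truth[0], mean[1] - truth[1]) < 1.0

    def test_single_azimuth_matches_rejection_sampling(self, rng):
        """One azimuth, kappa fixed: MCMC marginals must match direct rejection
        sampling of the unnormalized posterior (KS, alpha=0.01)."""
        z = np.array([0.0, 0.0])
        bearing = 0.6
        kappa = 100.0
        r = 500.0
        obs = _obs([(0, z[0], z[1], bearing)])
        post = fit_atm(obs, KappaModel(homogeneous=True, mu_beta=np.log(kappa),
                                       sigma2_beta=1e-8),
                       radius_r=r, mcmc=MCMCConfig(n_iter=40_000, seed=4))
        draws = post.locations[0].draws
        assert np.mean(post.locations[0].support.contains(draws)) >= 0.99
        # oracle: uniform support draws accepted with prob exp(loglik - max)
        sup = SupportRegion([z], r)
        cand = sup.sample(200_000, rng)
        tt = np.arctan2(cand[:, 1], cand[:, 0])
        ll = kappa * np.cos(bearing - tt)
        keep = rng.uniform(size=len(cand)) < np.exp(ll - kappa)
        ref = cand[keep]
        # thin the chain to roughly independent draws before the KS test
        thin = draws[:: max(1, len(draws) // 400)]
        for dim in (0, 1):
            p = kstest(thin[:, dim], lambda q, d=dim: np.searchsorted(
                np.sort(ref[:, d]), q) / len(ref)).pvalue
            assert p > 0.01

    def test_all_draws_inside_support(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.0, 0.0])
        stations = rng.normal(size=(3, 2)) * 300
        obs = _obs([
            (0, z[0], z[1], vonmises_sample(expected_bearing(truth, z), 50.0, rng))
            for z in stations
        ])
        post = fit_atm(obs, KappaModel(homogeneous=True), radius_r=800.0,
                       mcmc=MCMCConfig(n_iter=3000, seed=6))
        loc = post.locations[0]
        assert np.all(loc.support.contains(loc.draws))

    def test_non_intersecting_azimuths_proper_posterior(self):
        # two parallel azimuths pointing away from each other
        obs = _obs([(0, 0.0, 0.0, 0.0), (0, 0.0, 200.0, np.pi)])
        post = fit_atm(obs, KappaModel(homogeneous=True), radius_r=600.0,
                       mcmc=MCMCConfig(n_iter=4000, seed=7))
        loc = post.locations[0]
        assert np.all(np.isfinite(loc.draws))
        assert np.all(loc.support.contains(loc.draws))
        assert loc.draws.std(axis=0).max() > 10.0  # diffuse but proper

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        obs = _obs([
            (i, 300 * np.cos(a), 300 * np.sin(a),
             wrap_angle(np.pi + a + rng.normal() * 0.1))
            for i in range(3) for a in rng.uniform(-np.pi, np.pi, 3)
        ])
        kw = dict(radius_r=600.0, mcmc=MCMCConfig(n_iter=1500, seed=99))
        p1 = fit_atm(obs, KappaModel(homogeneous=True), **kw)
        p2 = fit_atm(obs, KappaModel(homogeneous=True), **kw)
        for k in p1.locations:
            np.testing.assert_array_equal(p1.locations[k].draws, p2.locations[k].draws)
        np.testing.assert_array_equal(p1.beta, p2.beta)

    def test_kappa_sharing_shrinks_single_azimuth_posterior(self):
        """A single-azimuth relocation fit jointly with many well-determined
        relocations borrows kappa information and tightens."""
        rng = np.random.default_rng(9)
        kappa = 200.0
        rows = [(0, 0.0, 0.0, float(vonmises_sample(0.6, kappa, rng)))]
        for i in range(1, 40):
            truth = rng.uniform(-2000, 2000, size=2)
            ang = rng.uniform(-np.pi, np.pi, size=3)
            for a in ang:
                z = truth + 400 * np.array([np.cos(a), np.sin(a)])
                rows.append(
                    (i, z[0], z[1],
                     float(vonmises_sample(expected_bearing(truth, z), kappa, rng)))
                )
        alone = fit_atm(_obs(rows[:1]), KappaModel(homogeneous=True), radius_r=600.0,
                        mcmc=MCMCConfig(n_iter=6000, seed=10))
        joint = fit_atm(_obs(rows), KappaModel(homogeneous=True), radius_r=600.0,
                        mcmc=MCMCConfig(n_iter=6000, seed=11))
        sd_alone = alone.locations[0].draws.std(axis=0).mean()
        sd_joint = joint.locations[0].draws.std(axis=0).mean()
        assert sd_joint < sd_alone

    def test_structured_failures(self):
        with pytest.raises(AtmDataError):
            fit_atm(_obs([]), radius_r=100.0)
        obs = _obs([(0, 0.0, 0.0, 0.1)])
        obs["flat"] = 1.0  # duplicates the intercept -> rank deficient
        with pytest.raises(AtmDataError):
            fit_atm(obs, KappaModel(covariates=("flat",)), radius_r=100.0)
        with pytest.raises(AtmDataError):
            fit_atm(_obs([(0, 0.0, 0.0, 0.1)]))  # no radius, no support


class TestHierarchicalKappa:
    def test_beta_and_sigma_recovered_roughly(self):
        """Intercept-only hierarchy: posterior for beta0 concentrates near the
        generating value with many azimuths."""
        rng = np.random.default_rng(12)
        beta0, s2 = 4.6, 0.25
        rows = []
        for i in range(80):
            truth = rng.uniform(-5000, 5000, size=2)
            for a in rng.uniform(-np.pi, np.pi, size=3):
                z = truth + rng.uniform(100, 600) * np.array([np.cos(a), np.sin(a)])
                kap = np.exp(rng.normal(beta0, np.sqrt(s2)))
                rows.append((i, z[0], z[1],
                             float(vonmises_sample(expected_bearing(truth, z), kap, rng))))
        post = fit_atm(_obs(rows), KappaModel(), radius_r=700.0,
                       mcmc=MCMCConfig(n_iter=6000, seed=13))
        b = post.beta[:, 0]
        lo, hi = np.percentile(b, [2.5, 97.5])
        assert lo - 0.5 < beta0 < hi + 0.5

    def test_distance_effect_runs_and_is_finite(self):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(25):
            truth = rng.uniform(-3000, 3000, size=2)
            for a in rng.uniform(-np.pi, np.pi, size=3):
                z = truth + rng.uniform(100, 900) * np.array([np.cos(a), np.sin(a)])
                rows.append((i, z[0], z[1],
                             float(vonmises_sample(expected_bearing(truth, z), 60.0, rng))))
        post = fit_atm(_obs(rows), KappaModel(distance_effect=True), radius_r=1000.0,
                       mcmc=MCMCConfig(n_iter=2000, seed=15))
        assert post.alpha1 is not None and np.all(np.isfinite(post.alpha1))


class TestHPD:
    def test_normal_draws_area_matches_closed_form(self, rng):
        cov = np.array([[9.0, 2.0], [2.0, 4.0]])
        draws = rng.multivariate_normal([10.0, -5.0], cov, size=10_000)
        region = HPDRegion(draws, 0.95)
        want = np.pi * chi2.ppf(0.95, 2) * np.sqrt(np.linalg.det(cov))
        assert region.area == pytest.approx(want, rel=0.05)

    def test_nesting_and_monotone_contains(self, rng):
        draws = rng.multivariate_normal([0.0, 0.0], np.eye(2), size=4000)
        r50 = HPDRegion(draws, 0.50)
        r95 = HPDRegion(draws, 0.95)
        assert r50.threshold >= r95.threshold  # 50% region nested in 95%
        pts = rng.normal(size=(200, 2)) * 2
        for p in pts:
            if r50.contains(p):
                assert r95.contains(p)

    def test_degenerate_posterior_point_region(self):
        draws = np.tile([3.0, 4.0], (100, 1))
        region = HPDRegion(draws, 0.95, grid_resolution=0.5)
        assert region.contains((3.0, 4.0))
        assert not region.contains((10.0, 10.0))

    def test_hpd_isopleth_from_location_posterior(self, rng):
        from azitel.atm import LocationPosterior

        sup = SupportRegion([(0.0, 0.0)], 50.0)
        draws = rng.multivariate_normal([0, 0], 25 * np.eye(2), size=3000)
        draws = draws[sup.contains(draws)]
        loc = LocationPosterior(relocation=0, draws=draws, acceptance_rate=0.3,
                                support=sup)
        region = hpd_isopleth(loc, 0.95)
        assert region.contains(np.array([0.0, 0.0]))
        assert region.area > 0
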