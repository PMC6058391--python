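"""GRF covariates, point-process sampling, RSF likelihood and fits."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chisquare

from azitel.atm import MCMCConfig
from azitel.rsf import (
    Availability,
    RSFHyperpriors,
    fit_atm_rsf,
    fit_hier_rsf,
    fit_rsf,
    rsf_log_likelihood,
    sample_ipp_locations,
    simulate_grf_covariates,
)


@pytest.fixture
def raster(rng):
    return simulate_grf_covariates(30, 30, 25.0, "moderate", rng)


class TestGRF:
    def test_categorical_balanced(self, rng):
        r = simulate_grf_covariates(40, 40, 25.0, "low", rng)
        frac = r.layers["categorical"].mean()
        assert frac == pytest.approx(0.5, abs=1.0 / 40)

    def test_continuous_standardized(self, rng):
        means, vars_ = [], []
        for _ in range(20):
            r = simulate_grf_covariates(40, 40, 25.0, "moderate", rng)
            means.append(r.layers["continuous"].mean())
            vars_.append(r.layers["continuous"].var())
        assert np.mean(means) == pytest.approx(0.0, abs=0.02)
        assert np.mean(vars_) == pytest.approx(1.0, abs=0.05)

    def test_autocorrelation_range_ordering(self, rng):
        """Lag-2 spatial correlation must rise from low to high settings."""
        corr = {}
        for level in ("low", "moderate", "high"):
            cs = []
            for _ in range(20):
                f = simulate_grf_covariates(40, 40, 25.0, level, rng).layers["continuous"]
                cs.append(np.corrcoef(f[:, :-2].ravel(), f[:, 2:].ravel())[0, 1])
            corr[level] = np.mean(cs)
        assert corr["low"] < corr["moderate"] < corr["high"]

    def test_bad_level_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_grf_covariates(10, 10, 25.0, "extreme", rng)


class TestIPPSampling:
    def test_gamma_zero_uniform(self, rng, raster):
        av = Availability(raster)
        pts = sample_ipp_locations([0.0, 0.0], av, 10_000, rng)
        idx = av.avail_index(pts)
        assert np.all(idx >= 0)
        counts = np.bincount(idx, minlength=av.X.shape[0])
        assert chisquare(counts).pvalue > 0.01

    def test_binary_intensity_ratio(self, rng, raster):
        av = Availability(raster)
        g = 1.2
        pts = sample_ipp_locations([0.0, g], av, 40_000, rng)
        cat = av.covariates_at(pts)[:, 1]
        n1, n0 = (cat == 1).sum(), (cat == 0).sum()
        c1 = (av.X[:, 1] == 1).sum()
        c0 = (av.X[:, 1] == 0).sum()
        ratio = (n1 / c1) / (n0 / c0)  # per-cell intensity ratio
        assert ratio == pytest.approx(np.exp(g), rel=0.08)

    def test_all_samples_inside_availability(self, rng, raster):
        hull_pts = rng.uniform(150, 550, size=(12, 2))
        av = Availability.from_hull(raster, hull_pts)
        pts = sample_ipp_locations([0.5, -0.5], av, 2000, rng)
        assert np.all(av.avail_index(pts) >= 0)


class TestLogLikelihood:
    def test_gamma_zero_is_minus_n_log_area(self, rng, raster):
        av = Availability(raster)
        pts = sample_ipp_locations([0.0, 0.0], av, 50, rng)
        ll = rsf_log_likelihood([0.0, 0.0], pts, av)
        assert ll == pytest.approx(-50 * np.log(av.area), rel=1e-12)

    def test_covariate_shift_invariance(self, rng):
        """Adding a constant to a covariate leaves the weighted density
        unchanged (tested without standardization, which would absorb it)."""
        r1 = simulate_grf_covariates(20, 20, 10.0, "moderate", np.random.default_rng(3))
        layers2 = {k: v.copy() for k, v in r1.layers.items()}
        layers2["continuous"] = layers2["continuous"] + 5.0
        from azitel.rsf import CovariateRaster

        r2 = CovariateRaster(r1.xllcorner, r1.yllcorner, r1.cellsize, layers2)
        av1 = Availability(r1, standardize=False)
        av2 = Availability(r2, standardize=False)
        pts = sample_ipp_locations([0.7, 0.2], av1, 100, rng)
        g = np.array([0.7, 0.2])
        d1 = rsf_log_likelihood(g, pts, av1)
        d2 = rsf_log_likelihood(g, pts, av2)
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_matches_cell_sum_oracle(self, rng):
        r = simulate_grf_covariates(20, 20, 10.0, "moderate", rng)
        av = Availability(r)
        pts = sample_ipp_locations([0.5, 0.5], av, 30, rng)
        for _ in range(5):
            g = rng.normal(size=2)
            # independent double-loop over cells
            total = 0.0
            xs, ys = r.cell_centers()
            for iy in range(20):
                for ix in range(20):
                    x = (np.array([r.layers["continuous"][iy, ix],
                                   r.layers["categorical"][iy, ix]])
                         - av.offsets) / av.scales
                    total += np.exp(x @ g) * r.cellsize**2
            Xp = av.covariates_at(pts)
            want = float(np.sum(Xp @ g) - len(pts) * np.log(total))
            assert rsf_log_likelihood(g, pts, av) == pytest.approx(want, abs=1e-10)

    def test_outside_availability_rejected(self, rng, raster):
        av = Availability(raster)
        with pytest.raises(ValueError):
            rsf_log_likelihood([0.0, 0.0], np.array([[-1e6, -1e6]]), av)

    def test_posterior_mode_matches_numerical_optimizer(self, rng):
        """Flat-ish prior RSF posterior mode vs independent BFGS optimum."""
        r = simulate_grf_covariates(25, 25, 20.0, "moderate", rng)
        av = Availability(r)
        g_true = np.array([0.8, -0.5])
        pts = sample_ipp_locations(g_true, av, 400, rng)
        post = fit_rsf(pts, av, RSFHyperpriors(sigma2_0=1e6),
                       mcmc=MCMCConfig(n_iter=6000, seed=2))
        med = np.median(post.gamma[:, 0, :], axis=0)
        opt = minimize(lambda g: -rsf_log_likelihood(g, pts, av), np.zeros(2),
                       method="BFGS")
        np.testing.assert_allclose(med, opt.x, atol=0.12)


class TestFits:
    def test_flat_covariate_centers_at_zero(self, rng):
        r = simulate_grf_covariates(20, 20, 25.0, "moderate", rng)
        av = Availability(r)
        pts = sample_ipp_locations([0.0, 0.0], av, 300, rng)
        post = fit_rsf(pts, av, mcmc=MCMCConfig(n_iter=4000, seed=3))
        med = np.median(post.gamma[:, 0, :], axis=0)
        sd = post.gamma[:, 0, :].std(axis=0)
        assert np.all(np.abs(med) < 3 * sd + 0.1)

    def test_more_data_shrinks_posterior(self, rng):
        r = simulate_grf_covariates(25, 25, 20.0, "moderate", rng)
        av = Availability(r)
        g = np.array([1.0, 0.5])
        sds = []
        for n in (50, 200):
            pts = sample_ipp_locations(g, av, n, rng)
            post = fit_rsf(pts, av, mcmc=MCMCConfig(n_iter=4000, seed=4))
            sds.append(post.gamma[:, 0, 0].std())
        assert sds[1] < sds[0]

    def test_hierarchical_structure_present(self, rng):
        r = simulate_grf_covariates(20, 20, 20.0, "moderate", rng)
        av = Availability(r)
        locs = {i: sample_ipp_locations([1.0, 0.3], av, 80, rng) for i in range(3)}
        post = fit_hier_rsf(locs, av, mcmc=MCMCConfig(n_iter=2000, seed=5))
        assert post.mu_gamma is not None and post.sigma_gamma is not None
        assert post.gamma.shape[1] == 3
        # population mean tracks the individuals
        assert abs(np.median(post.mu_gamma[:, 0]) - 1.0) < 0.6


class TestAtmRsf:
    def _make_azimuth_data(self, truths, rng, kappa=50.0):
        import pandas as pd

        from azitel.circular import expected_bearing, vonmises_sample

        rows = []
        for i, t in enumerate(truths):
            for a in rng.uniform(-np.pi, np.pi, size=3):
                z = t + rng.uniform(80, 250) * np.array([np.cos(a), np.sin(a)])
                b = float(vonmises_sample(expected_bearing(t, z), kappa, rng))
                rows.append((i, z[0], z[1], b))
        return pd.DataFrame(rows, columns=["relocation", "station_x", "station_y",
                                           "bearing"])

    def test_gamma_zero_reduces_to_plain_atm(self, rng):
        from scipy.stats import ks_2samp

        from azitel.atm import KappaModel, fit_atm

        r = simulate_grf_covariates(40, 40, 25.0, "high", rng)
        av = Availability(r)
        truths = rng.uniform(300, 700, size=(6, 2))
        obs = self._make_azimuth_data(truths, rng)
        cfg = MCMCConfig(n_iter=6000, seed=6)
        km = KappaModel(homogeneous=True)
        plain = fit_atm(obs, km, radius_r=300.0, mcmc=cfg)
        joint, _ = fit_atm_rsf(obs, av, kappa_model=km, radius_r=300.0,
                               mcmc=cfg, fix_gamma=[0.0, 0.0])
        for rid in plain.locations:
            a = plain.locations[rid].draws[::20]
            b = joint.locations[rid].draws[::20]
            for dim in (0, 1):
                assert ks_2samp(a[:, dim], b[:, dim]).pvalue > 0.005

    def test_strong_selection_reduces_location_dispersion(self, rng):
        """Selection feedback: informative covariates shrink the location
        posterior relative to the uniform-prior ATM."""
        from azitel.atm import KappaModel, fit_atm

        r = simulate_grf_covariates(40, 40, 25.0, "moderate", np.random.default_rng(11))
        av = Availability(r)
        g = np.array([2.0, 1.5])
        truths = sample_ipp_locations(g, av, 25, rng)
        obs = self._make_azimuth_data(truths, rng, kappa=25.0)
        km = KappaModel(homogeneous=True)
        plain = fit_atm(obs, km, radius_r=300.0, mcmc=MCMCConfig(n_iter=5000, seed=7))
        joint, _ = fit_atm_rsf(obs, av, kappa_model=km, radius_r=300.0,
                               mcmc=MCMCConfig(n_iter=5000, seed=8), fix_gamma=g)
        disp = lambda p: np.mean([np.trace(np.cov(p.locations[i].draws.T))
                                  for i in p.locations])
        assert disp(joint) < disp(plain)

    def test_joint_fit_recovers_selection_sign(self, rng):
        r = simulate_grf_covariates(40, 40, 25.0, "high", np.random.default_rng(21))
        av = Availability(r)
        g = np.array([1.5, 0.0])
        truths = sample_ipp_locations(g, av, 60, rng)
        obs = self._make_azimuth_data(truths, rng, kappa=100.0)
        _, rsf_post = fit_atm_rsf(obs, av, radius_r=300.0,
                                  mcmc=MCMCConfig(n_iter=6000, seed=9))
        med = np.median(rsf_post.gamma[:, 0, 0])
        assert med > 0.4  # strongly positive continuous selection recovered
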