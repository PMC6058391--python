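"""Hierarchical Bayesian azimuthal telemetry model (ATM).

The observation model treats each recorded azimuth ``theta`` from a known
station ``z`` toward an unknown animal location ``mu`` as von Mises about the
true bearing ``theta_tilde = atan2(mu_y - z_y, mu_x - z_x)`` with
concentration ``kappa``. Concentrations are modeled hierarchically on the
log scale::

    log(kappa_a) ~ Normal(w_a' beta + alpha1 * log d_a, sigma2_kappa)

with an optional log-distance effect ``alpha1`` (``d_a`` the station-animal
distance), coefficient prior ``beta ~ N(mu_beta, Sigma_beta)`` and variance
prior ``sigma2_kappa ~ InvGamma(a_sigma, b_sigma)``. Each location carries a
uniform prior over the union of circles of radius ``r`` centred on its
stations, which keeps the posterior proper even for a single azimuth or
non-intersecting azimuths.

Fitting is Metropolis-within-Gibbs: random-walk updates for locations
(rejected outside the support) and per-azimuth log-concentrations,
conjugate draws for ``beta`` and ``sigma2_kappa``, and a random walk for
``alpha1``. Proposal scales adapt toward a 20-45% acceptance rate during
burn-in and are then frozen, so a fixed seed reproduces the chain exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0e

__all__ = [
    "KappaModel",
    "MCMCConfig",
    "SupportRegion",
    "LocationPosterior",
    "ATMPosterior",
    "HPDRegion",
    "AtmDataError",
    "build_support",
    "default_radius",
    "fit_atm",
    "hpd_isopleth",
    "effective_sample_size",
]


class AtmDataError(ValueError):
    """Raised for unusable inputs: empty data, rank-deficient design, bad support."""


@dataclass
class KappaModel:
    """Concentration model for the bearing errors.

    Default is the full hierarchy: per-azimuth ``log kappa`` normal about a
    covariate mean with variance ``sigma2_kappa``. With ``homogeneous=True``
    a single ``kappa`` is shared by every azimuth (the benchmark-simulation
    assumption), with prior ``log kappa ~ N(mu_beta, sigma2_beta)``; the
    hierarchy's variance and covariates are then unused.
    """

    covariates: tuple[str, ...] = ()  # azimuth-table columns entering w (intercept implied)
    distance_effect: bool = False  # include alpha1 * log(d)
    homogeneous: bool = False
    mu_beta: np.ndarray | float = 0.0
    sigma2_beta: float = 4.0  # diagonal of Sigma_beta
    a_sigma: float = 2.0  # inverse-gamma shape for sigma2_kappa
    b_sigma: float = 1.0  # inverse-gamma scale
    alpha1_prior_var: float = 4.0


@dataclass
class MCMCConfig:
    n_iter: int = 10_000
    burn_in: int | None = None  # default 20% of n_iter
    thin: int = 1
    seed: int = 0
    mu_proposal_scale: float | None = None  # default radius/10
    logkappa_proposal_scale: float = 0.5
    alpha1_proposal_scale: float = 0.1
    adapt_interval: int = 50

    @property
    def n_burn(self) -> int:
        return int(0.2 * self.n_iter) if self.burn_in is None else self.burn_in


class SupportRegion:
    """Union of circles of radius r around a relocation's observer stations."""

    def __init__(self, stations, radius_r: float):
        stations = np.atleast_2d(np.asarray(stations, dtype=float))
        if radius_r <= 0:
            raise ValueError("radius_r must be > 0")
        if len(stations) < 1:
            raise ValueError("need at least one station")
        if not np.all(np.isfinite(stations)):
            raise ValueError("non-finite station coordinates")
        self.stations = stations
        self.radius_r = float(radius_r)
        lo = stations.min(axis=0) - radius_r
        hi = stations.max(axis=0) + radius_r
        self.bounding_box = (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))

    def contains(self, points) -> np.ndarray | bool:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.stations[None, :, :]) ** 2).sum(axis=2)
        inside = (d2.min(axis=1) <= self.radius_r**2)
        if np.ndim(points) == 1:
            return bool(inside[0])
        return inside

    def area(self, n_mc: int = 200_000, seed: int = 0) -> float:
        """Union area; analytic for one or two circles, Monte Carlo otherwise."""
        r = self.radius_r
        if len(self.stations) == 1:
            return float(np.pi * r * r)
        if len(self.stations) == 2:
            d = float(np.linalg.norm(self.stations[0] - self.stations[1]))
            if d >= 2 * r:
                return float(2 * np.pi * r * r)
            # lens area of two equal circles
            lens = 2 * r * r * np.arccos(d / (2 * r)) - 0.5 * d * np.sqrt(4 * r * r - d * d)
            return float(2 * np.pi * r * r - lens)
        x0, y0, x1, y1 = self.bounding_box
        rng = np.random.default_rng(seed)
        pts = rng.uniform((x0, y0), (x1, y1), size=(n_mc, 2))
        frac = np.mean(self.contains(pts))
        return float(frac * (x1 - x0) * (y1 - y0))

    def sample(self, n: int, rng) -> np.ndarray:
        """Uniform draws over the union by rejection from the bounding box."""
        x0, y0, x1, y1 = self.bounding_box
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(2 * (n - len(out)), 64)
            pts = rng.uniform((x0, y0), (x1, y1), size=(m, 2))
            out = np.vstack([out, pts[self.contains(pts)]])
        return out[:n]


def build_support(stations, radius_r: float) -> SupportRegion:
    return SupportRegion(stations, radius_r)


def default_radius(stations) -> float:
    """Helper default for r: 3x the 95th percentile of pairwise station spacing."""
    stations = np.atleast_2d(np.asarray(stations, dtype=float))
    if len(stations) < 2:
        raise ValueError("need >= 2 stations to derive a default radius; set r explicitly")
    d = np.sqrt(((stations[:, None, :] - stations[None, :, :]) ** 2).sum(axis=2))
    pair = d[np.triu_indices(len(stations), k=1)]
    return float(3.0 * np.percentile(pair, 95))


@dataclass
class LocationPosterior:
    relocation: object
    draws: np.ndarray  # (n_draws, 2) post burn-in, thinned
    acceptance_rate: float
    support: SupportRegion

    @property
    def ess(self) -> float:
        return min(effective_sample_size(self.draws[:, 0]),
                   effective_sample_size(self.draws[:, 1]))

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)


@dataclass
class ATMPosterior:
    locations: dict  # relocation id -> LocationPosterior
    beta: np.ndarray  # (n_draws, p)
    sigma2_kappa: np.ndarray  # (n_draws,)
    alpha1: np.ndarray | None
    logkappa_mean: np.ndarray  # posterior mean of log kappa per azimuth
    acceptance: dict
    config: MCMCConfig
    design_columns: tuple[str, ...] = ()
    relocation_index: pd.DataFrame | None = None

    def location_draw_matrix(self) -> tuple[list, np.ndarray]:
        """Relocation ids and the aligned draw array of shape (n_draws, K, 2)."""
        ids = list(self.locations)
        arr = np.stack([self.locations[i].draws for i in ids], axis=1)
        return ids, arr


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial positive sequence of autocorrelations (Geyer 1992)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    v = np.sum(x * x)
    if v == 0:
        return float(n)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / v
    # sum consecutive pairs until a pair goes non-positive
    s = 0.0
    for k in range(1, n // 2):
        pair = acov[2 * k - 1] + acov[2 * k]
        if pair <= 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _log_i0(k):
    return np.log(i0e(k)) + k


_LK_MIN, _LK_MAX = -10.0, 20.0


def _prepare(observations: pd.DataFrame, kappa_model: KappaModel):
    if observations is None or len(observations) == 0:
        raise AtmDataError("no azimuth observations")
    required = {"relocation", "station_x", "station_y", "bearing"}
    missing = required - set(observations.columns)
    if missing:
        raise AtmDataError(f"missing columns: {sorted(missing)}")
    obs = observations.reset_index(drop=True)
    # contiguous segments per relocation, preserving first-appearance order
    reloc_ids = list(dict.fromkeys(obs["relocation"]))
    order = np.argsort([reloc_ids.index(r) for r in obs["relocation"]], kind="stable")
    obs = obs.iloc[order].reset_index(drop=True)
    codes = np.asarray([reloc_ids.index(r) for r in obs["relocation"]])
    starts = np.searchsorted(codes, np.arange(len(reloc_ids)))

    z = obs[["station_x", "station_y"]].to_numpy(float)
    theta = obs["bearing"].to_numpy(float)
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(theta)):
        raise AtmDataError("non-finite station coordinates or bearings")

    cols = ["intercept", *kappa_model.covariates]
    W = np.column_stack(
        [np.ones(len(obs))] + [obs[c].to_numpy(float) for c in kappa_model.covariates]
    )
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise AtmDataError("rank-deficient kappa design matrix")
    return obs, reloc_ids, codes, starts, z, theta, W, tuple(cols)


def fit_atm(
    observations: pd.DataFrame,
    kappa_model: KappaModel | None = None,
    support=None,
    radius_r: float | None = None,
    mcmc: MCMCConfig | None = None,
    location_log_weight=None,
    sweep_hook=None,
) -> ATMPosterior:
    """Fit the ATM jointly to all relocations in ``observations``.

    Parameters
    ----------
    observations : DataFrame with columns ``relocation``, ``station_x``,
        ``station_y``, ``bearing`` (math radians) and any kappa covariates.
        An ``individual`` column is carried through if present.
    support : optional dict mapping relocation id -> SupportRegion; built
        from each relocation's own stations and ``radius_r`` when omitted.
    radius_r : maximum detection distance r (meters); required unless
        ``support`` is given. Use :func:`default_radius` for a data-driven
        default.
    location_log_weight : optional callable ``f(points) -> log-weights`` that
        tilts the location prior inside the support (used by the joint
        ATM-RSF model); ``None`` keeps the uniform prior.
    sweep_hook : optional callable ``hook(it, mu, rng)`` run once per
        iteration after the location update. It may mutate the state behind
        ``location_log_weight`` (e.g. draw new selection coefficients); if it
        returns an array, that array replaces the cached per-relocation log
        weights at the current locations.

    Returns an :class:`ATMPosterior`; identical config and seed reproduce the
    draws exactly.
    """
    kappa_model = kappa_model or KappaModel()
    mcmc = mcmc or MCMCConfig()
    homogeneous = bool(kappa_model.homogeneous)
    if homogeneous and (kappa_model.covariates or kappa_model.distance_effect):
        raise AtmDataError("homogeneous kappa excludes covariates and the distance effect")
    obs, reloc_ids, codes, starts, z, theta, W, cols = _prepare(observations, kappa_model)
    n_az = len(obs)
    K = len(reloc_ids)
    p = W.shape[1]

    if support is None:
        if radius_r is None:
            raise AtmDataError("radius_r is required when no support regions are given")
        supports = [
            SupportRegion(z[codes == k], radius_r) for k in range(K)
        ]
    else:
        supports = [support[r] for r in reloc_ids]
    r2 = np.asarray([s.radius_r**2 for s in supports])
    # concatenated support stations with segment starts, so the union-of-circles
    # membership test vectorizes across relocations whatever the support source
    sup_stations = np.vstack([s.stations for s in supports])
    sup_len = np.asarray([len(s.stations) for s in supports])
    sup_starts = np.concatenate([[0], np.cumsum(sup_len)[:-1]])
    sup_codes = np.repeat(np.arange(K), sup_len)
    sup_r2 = np.repeat(r2, sup_len)

    rng = np.random.default_rng(mcmc.seed)

    # --- initial state ---------------------------------------------------
    # location: centroid of each relocation's stations nudged inside support
    mu = np.empty((K, 2))
    for k in range(K):
        c = z[codes == k].mean(axis=0)
        if not supports[k].contains(c):
            c = supports[k].sample(1, rng)[0]
        mu[k] = c
    mu_beta = np.broadcast_to(np.asarray(kappa_model.mu_beta, dtype=float), (p,)).copy()
    prior_prec_beta = np.eye(p) / kappa_model.sigma2_beta
    beta = mu_beta.copy()
    sigma2 = 1.0
    alpha1 = 0.0
    use_alpha = bool(kappa_model.distance_effect)
    logkappa = np.clip(np.atleast_1d(W @ beta), _LK_MIN, _LK_MAX).astype(float)

    # proposal scales
    s_mu = np.full(K, mcmc.mu_proposal_scale
                   or 0.1 * float(np.sqrt(r2.mean())))
    s_lk = np.full(n_az, mcmc.logkappa_proposal_scale)
    s_a1 = mcmc.alpha1_proposal_scale

    seg_add = lambda v: np.add.reduceat(v, starts)

    def az_loglik(mu_arr, kappa):
        """Per-azimuth von Mises term and per-azimuth distances for mu_arr (K,2)."""
        dxy = mu_arr[codes] - z
        d2 = (dxy**2).sum(axis=1)
        tt = np.arctan2(dxy[:, 1], dxy[:, 0])
        ll = kappa * np.cos(theta - tt) - _log_i0(kappa)
        return ll, d2, tt

    kappa = np.exp(logkappa)
    ll_az, d2_cur, tt_cur = az_loglik(mu, kappa)
    cosres = np.cos(theta - tt_cur)
    if location_log_weight is not None:
        lw_cur = np.asarray(location_log_weight(mu), dtype=float)
        for k in np.flatnonzero(~np.isfinite(lw_cur)):
            # initial point carries zero prior weight (e.g. outside availability):
            # restart it from an admissible support draw
            for cand in supports[k].sample(256, rng):
                w = float(np.asarray(location_log_weight(cand[None, :]))[0])
                if np.isfinite(w):
                    mu[k] = cand
                    lw_cur[k] = w
                    break
            else:
                raise AtmDataError(
                    f"support of relocation {reloc_ids[k]!r} carries no prior mass"
                )
        ll_az, d2_cur, tt_cur = az_loglik(mu, kappa)
        cosres = np.cos(theta - tt_cur)
    else:
        lw_cur = np.zeros(K)

    n_save = (mcmc.n_iter - mcmc.n_burn + mcmc.thin - 1) // mcmc.thin
    mu_draws = np.empty((n_save, K, 2))
    beta_draws = np.empty((n_save, p))
    sigma2_draws = np.empty(n_save)
    alpha1_draws = np.empty(n_save) if use_alpha else None
    lk_accum = np.zeros(n_az)

    acc_mu = np.zeros(K)
    acc_lk = np.zeros(n_az)
    acc_a1 = 0.0
    win_mu = np.zeros(K)
    win_lk = np.zeros(n_az)
    win_a1 = 0.0
    n_a1_try = 0

    save_i = 0
    eps_d = 1e-6  # guards log d at (numerically) zero distance

    for it in range(mcmc.n_iter):
        # ---- locations ----
        prop = mu + rng.normal(size=(K, 2)) * s_mu[:, None]
        dxy_p = prop[codes] - z
        d2_p = (dxy_p**2).sum(axis=1)
        tt_p = np.arctan2(dxy_p[:, 1], dxy_p[:, 0])
        ll_p = kappa * np.cos(theta - tt_p)  # I0 term cancels (kappa unchanged)
        ll_c = kappa * np.cos(theta - tt_cur)
        if use_alpha:
            m_p = W @ beta + alpha1 * 0.5 * np.log(d2_p + eps_d)
            m_c = W @ beta + alpha1 * 0.5 * np.log(d2_cur + eps_d)
            ll_p = ll_p - (logkappa - m_p) ** 2 / (2 * sigma2)
            ll_c = ll_c - (logkappa - m_c) ** 2 / (2 * sigma2)
        delta = seg_add(ll_p - ll_c)
        sup_d2 = ((prop[sup_codes] - sup_stations) ** 2).sum(axis=1)
        inside = np.minimum.reduceat(sup_d2 - sup_r2, sup_starts) <= 0.0
        if location_log_weight is not None:
            lw_p = np.asarray(location_log_weight(prop), dtype=float)
            delta = delta + lw_p - lw_cur
        accept = inside & (np.log(rng.uniform(size=K)) < delta)
        mu[accept] = prop[accept]
        if location_log_weight is not None:
            lw_cur = np.where(accept, lw_p, lw_cur)
        acc_step = accept.astype(float)
        acc_mu += acc_step
        win_mu += acc_step
        upd = accept[codes]
        d2_cur = np.where(upd, d2_p, d2_cur)
        tt_cur = np.where(upd, tt_p, tt_cur)
        cosres = np.cos(theta - tt_cur)

        if sweep_hook is not None:
            new_lw = sweep_hook(it, mu, rng)
            if new_lw is not None:
                lw_cur = np.asarray(new_lw, dtype=float)

        # ---- log kappa ----
        if homogeneous:
            # single shared kappa: scalar random walk on log kappa with
            # prior N(mu_beta, sigma2_beta)
            lk = logkappa[0]
            lk_p_s = lk + rng.normal() * s_lk[0]
            if _LK_MIN < lk_p_s < _LK_MAX:
                kap_p_s = np.exp(lk_p_s)
                dlog = (
                    (kap_p_s - kappa[0]) * float(np.sum(cosres))
                    - n_az * (_log_i0(kap_p_s) - _log_i0(kappa[0]))
                    - ((lk_p_s - mu_beta[0]) ** 2 - (lk - mu_beta[0]) ** 2)
                    / (2 * kappa_model.sigma2_beta)
                )
                if np.log(rng.uniform()) < dlog:
                    logkappa[:] = lk_p_s
                    kappa = np.exp(logkappa)
                    acc_lk += 1.0
                    win_lk += 1.0
            beta = np.array([logkappa[0]])
            sigma2 = 0.0
        else:
            lk_p = logkappa + rng.normal(size=n_az) * s_lk
            ok = (lk_p > _LK_MIN) & (lk_p < _LK_MAX)
            kap_p = np.exp(np.clip(lk_p, _LK_MIN, _LK_MAX))
            m = W @ beta
            if use_alpha:
                m = m + alpha1 * 0.5 * np.log(d2_cur + eps_d)
            dlog = (
                (kap_p - kappa) * cosres
                - (_log_i0(kap_p) - _log_i0(kappa))
                - ((lk_p - m) ** 2 - (logkappa - m) ** 2) / (2 * sigma2)
            )
            acc = ok & (np.log(rng.uniform(size=n_az)) < dlog)
            logkappa = np.where(acc, lk_p, logkappa)
            kappa = np.exp(logkappa)
            acc_lk += acc
            win_lk += acc

            # ---- beta (conjugate normal) ----
            resid_target = logkappa - (
                alpha1 * 0.5 * np.log(d2_cur + eps_d) if use_alpha else 0.0
            )
            prec = W.T @ W / sigma2 + prior_prec_beta
            cov = np.linalg.inv(prec)
            mean = cov @ (W.T @ resid_target / sigma2 + prior_prec_beta @ mu_beta)
            beta = rng.multivariate_normal(mean, cov, method="cholesky")

            # ---- sigma2 (conjugate inverse-gamma) ----
            m = W @ beta + (alpha1 * 0.5 * np.log(d2_cur + eps_d) if use_alpha else 0.0)
            ss = float(np.sum((logkappa - m) ** 2))
            sigma2 = 1.0 / rng.gamma(kappa_model.a_sigma + 0.5 * n_az,
                                     1.0 / (kappa_model.b_sigma + 0.5 * ss))

        # ---- alpha1 (random walk) ----
        if use_alpha:
            a_p = alpha1 + rng.normal() * s_a1
            logd = 0.5 * np.log(d2_cur + eps_d)
            base = W @ beta
            ss_p = np.sum((logkappa - base - a_p * logd) ** 2)
            ss_c = np.sum((logkappa - base - alpha1 * logd) ** 2)
            dl = -(ss_p - ss_c) / (2 * sigma2) - (a_p**2 - alpha1**2) / (
                2 * kappa_model.alpha1_prior_var
            )
            n_a1_try += 1
            if np.log(rng.uniform()) < dl:
                alpha1 = a_p
                acc_a1 += 1
                win_a1 += 1

        # ---- adaptation (burn-in only) ----
        if it < mcmc.n_burn and (it + 1) % mcmc.adapt_interval == 0:
            rate_mu = win_mu / mcmc.adapt_interval
            s_mu *= np.exp(np.clip(rate_mu - 0.3, -0.5, 0.5))
            rate_lk = win_lk / mcmc.adapt_interval
            s_lk *= np.exp(np.clip(rate_lk - 0.35, -0.5, 0.5))
            if use_alpha:
                s_a1 *= np.exp(np.clip(win_a1 / mcmc.adapt_interval - 0.3, -0.5, 0.5))
            win_mu[:] = 0.0
            win_lk[:] = 0.0
            win_a1 = 0.0

        # ---- storage ----
        if it >= mcmc.n_burn and (it - mcmc.n_burn) % mcmc.thin == 0:
            mu_draws[save_i] = mu
            beta_draws[save_i] = beta
            sigma2_draws[save_i] = sigma2
            if use_alpha:
                alpha1_draws[save_i] = alpha1
            lk_accum += logkappa
            save_i += 1

    n_post = mcmc.n_iter - mcmc.n_burn
    locations = {
        reloc_ids[k]: LocationPosterior(
            relocation=reloc_ids[k],
            draws=mu_draws[:save_i, k, :].copy(),
            acceptance_rate=float(acc_mu[k] / mcmc.n_iter),
            support=supports[k],
        )
        for k in range(K)
    }
    reloc_index = obs.groupby("relocation", sort=False).first().reset_index()
    return ATMPosterior(
        locations=locations,
        beta=beta_draws[:save_i],
        sigma2_kappa=sigma2_draws[:save_i],
        alpha1=alpha1_draws[:save_i] if use_alpha else None,
        logkappa_mean=lk_accum / max(save_i, 1),
        acceptance={
            "mu": float(acc_mu.mean() / mcmc.n_iter),
            "logkappa": float(acc_lk.mean() / mcmc.n_iter),
            "alpha1": float(acc_a1 / max(n_a1_try, 1)) if use_alpha else None,
        },
        config=mcmc,
        design_columns=cols,
        relocation_index=reloc_index[
            [c for c in ("relocation", "individual") if c in reloc_index.columns]
        ],
    )


# ---------------------------------------------------------------------------
# HPD isopleths


class HPDRegion:
    """Highest-posterior-density region of a 2-D location posterior.

    Built from a Gaussian-product KDE of the draws with a single plug-in
    bandwidth; the threshold is the largest density value such that the
    fraction of draws whose density is >= it reaches ``level``, so the
    enclosed posterior mass (measured on the draws themselves) is >= level.
    """

    def __init__(self, draws: np.ndarray, level: float, support: SupportRegion | None = None,
                 grid_resolution: float | None = None, max_eval: int = 4000):
        if not (0.0 < level < 1.0):
            raise ValueError("level must be in (0, 1)")
        draws = np.asarray(draws, dtype=float)
        self.level = float(level)
        self.draws = draws
        n = len(draws)
        sd = np.sqrt(0.5 * (draws[:, 0].var() + draws[:, 1].var()))
        self.degenerate = sd < 1e-9
        if self.degenerate:
            self.point = draws.mean(axis=0)
            self.bandwidth = 0.0
            self.threshold = np.inf
            self._eval_pts = draws[:1]
            self.support = support
            self.grid_resolution = grid_resolution
            return
        # plug-in (normal-reference) bandwidth for a bivariate product kernel
        self.bandwidth = float(sd * n ** (-1.0 / 6.0))
        if n > max_eval:
            idx = np.linspace(0, n - 1, max_eval).astype(int)
            eval_pts = draws[idx]
        else:
            eval_pts = draws
        self._eval_pts = eval_pts
        dens = self.density(draws)
        # largest threshold with mass >= level  <=>  (1-level) quantile, rounded down
        k = int(np.floor((1.0 - level) * n))
        self.threshold = float(np.sort(dens)[max(k - 1, 0)] if k >= 1 else 0.0)
        self.support = support
        self.grid_resolution = grid_resolution
        self._grid = None

    def density(self, points) -> np.ndarray:
        """KDE density (built on the evaluation subset of draws) at points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.degenerate:
            return np.where(
                np.all(np.isclose(pts, self.point), axis=1), np.inf, 0.0
            )
        b = self.bandwidth
        ref = self._eval_pts
        out = np.empty(len(pts))
        step = max(1, int(2e7 // max(len(ref), 1)))
        for i in range(0, len(pts), step):
            chunk = pts[i : i + step]
            q = ((chunk[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2) / (2 * b * b)
            out[i : i + step] = np.exp(-q).sum(axis=1) / (len(ref) * 2 * np.pi * b * b)
        return out

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float)
        if self.degenerate:
            res = self.grid_resolution or 1e-6
            return bool(np.all(np.abs(point - self.point) <= res))
        return bool(self.density(point[None, :])[0] >= self.threshold)

    def _make_grid(self):
        if self._grid is not None:
            return self._grid
        draws = self.draws
        pad = 4 * self.bandwidth if not self.degenerate else 1.0
        x0, y0 = draws.min(axis=0) - pad
        x1, y1 = draws.max(axis=0) + pad
        res = self.grid_resolution or (np.hypot(x1 - x0, y1 - y0) / 200.0)
        xs = np.arange(x0, x1 + res, res)
        ys = np.arange(y0, y1 + res, res)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        dens = self.density(pts).reshape(gy.shape)
        if self.support is not None:
            mask = self.support.contains(pts).reshape(gy.shape)
            dens = np.where(mask, dens, 0.0)
        self._grid = (xs, ys, dens, res)
        return self._grid

    @property
    def area(self) -> float:
        """Area (m^2) of the region, counted on the evaluation grid."""
        if self.degenerate:
            return 0.0
        xs, ys, dens, res = self._make_grid()
        return float(np.count_nonzero(dens >= self.threshold) * res * res)


def hpd_isopleth(posterior: LocationPosterior | np.ndarray, level: float = 0.95,
                 grid_resolution: float | None = None) -> HPDRegion:
    """HPD region of a location posterior at the given mass level."""
    if isinstance(posterior, LocationPosterior):
        return HPDRegion(posterior.draws, level, support=posterior.support,
                         grid_resolution=grid_resolution)
    return HPDRegion(np.asarray(posterior, dtype=float), level,
                     grid_resolution=grid_resolution)
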