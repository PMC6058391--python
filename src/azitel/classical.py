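"""Classical triangulation estimators for azimuthal telemetry.

Implements the iteratively reweighted maximum-likelihood triangulation of
Lenth (1981), its robust Huber/Andrews M-estimator variants, a quasi-Newton
fit of the same objective (the algorithm Lenth advised against, as used by
some later software), and the naive component-wise average of pairwise
azimuth intersections. Asymptotic confidence ellipses come from the inverse
expected information at the optimum.

The bearing likelihood is von Mises: with expected bearing
``theta_tilde(mu)`` from station ``z`` toward candidate location ``mu``, the
objective minimized is ``sum_i w_i * (1 - cos(theta_i - theta_tilde_i(mu)))``.

Estimation failure (parallel azimuths, divergence, singular geometry) is a
*result*, not an exception: fits carry a ``converged`` flag so that benchmark
code can count successes the way telemetry studies report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .circular import (
    bessel_ratio,
    kappa_from_resultant,
    mean_resultant_length,
    ray_intersection,
    wrap_angle,
)

__all__ = [
    "TriangulationFit",
    "ConfidenceEllipse",
    "intersection_average",
    "triangulate",
    "confidence_ellipse",
    "METHODS",
]

METHODS = ("intersection-average", "mle-fixed-point", "mle-quasi-newton", "huber", "andrews")


@dataclass
class TriangulationFit:
    estimate: tuple[float, float] | None
    covariance: np.ndarray | None
    converged: bool
    n_iterations: int
    method: str
    kappa_hat: float | None = None
    message: str = ""
    n_azimuths: int = 0

    @property
    def has_covariance(self) -> bool:
        return self.covariance is not None


@dataclass
class ConfidenceEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    level: float
    covariance: np.ndarray = field(repr=False, default=None)

    @property
    def area(self) -> float:
        a, b = self.semi_axes
        return float(np.pi * a * b)

    def contains(self, point) -> bool:
        d = np.asarray(point, dtype=float) - np.asarray(self.center)
        q = float(d @ np.linalg.solve(self.covariance, d))
        return q <= chi2.ppf(self.level, df=2)

    def boundary(self, n: int = 128) -> np.ndarray:
        """Polygon approximation of the ellipse boundary, shape (n, 2)."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        ca, sa = np.cos(self.orientation), np.sin(self.orientation)
        x = a * np.cos(t)
        y = b * np.sin(t)
        return np.column_stack(
            [self.center[0] + ca * x - sa * y, self.center[1] + sa * x + ca * y]
        )


def _as_arrays(azimuths):
    stations = np.asarray([np.asarray(z, dtype=float) for z, _ in azimuths])
    bearings = np.asarray([float(b) for _, b in azimuths])
    return stations, bearings


def intersection_average(azimuths, fallback_to_lines: bool = True):
    """Component-wise mean of all pairwise forward-ray azimuth intersections.

    Pairs whose rays do not cross forward are dropped; if no pair crosses and
    ``fallback_to_lines`` is set, infinite-line intersections are averaged
    instead. Returns ``None`` when no intersection exists at all.
    """
    stations, bearings = _as_arrays(azimuths)
    n = len(bearings)
    if n < 2:
        raise ValueError("need at least 2 azimuths")
    for rays in ([True, False] if fallback_to_lines else [True]):
        pts = []
        for i in range(n):
            for j in range(i + 1, n):
                if np.all(stations[i] == stations[j]):
                    continue
                p = ray_intersection(stations[i], bearings[i], stations[j], bearings[j], rays=rays)
                if p is not None:
                    pts.append(p)
        if pts:
            m = np.mean(np.asarray(pts), axis=0)
            return (float(m[0]), float(m[1]))
    return None


def _objective(mu, stations, bearings, weights=None):
    tt = np.arctan2(mu[1] - stations[:, 1], mu[0] - stations[:, 0])
    r = 1.0 - np.cos(bearings - tt)
    if weights is None:
        return float(np.sum(r))
    return float(np.sum(weights * r))


def _default_init(stations, bearings):
    p = intersection_average(list(zip(stations, bearings)), fallback_to_lines=True)
    if p is not None:
        return np.asarray(p, dtype=float)
    # no crossings anywhere: start from the station centroid pushed along the
    # mean bearing direction by the mean pairwise station spacing
    c = stations.mean(axis=0)
    mb = np.arctan2(np.mean(np.sin(bearings)), np.mean(np.cos(bearings)))
    if len(stations) > 1:
        d = np.mean(
            [np.linalg.norm(a - b) for i, a in enumerate(stations) for b in stations[i + 1 :]]
        )
    else:
        d = 1.0
    return c + max(d, 1.0) * np.array([np.cos(mb), np.sin(mb)])


def _psi_weights(t, method, c):
    """M-estimator weight psi(t)/t; identity (all ones) for the plain MLE."""
    if method in ("mle-fixed-point", "mle-quasi-newton"):
        return np.ones_like(t)
    at = np.abs(t)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "huber":
            w = np.where(at <= c, 1.0, c / at)
        elif method == "andrews":
            w = np.where(at <= c * np.pi, np.sin(t / c) / (t / c), 0.0)
            w = np.where(at < 1e-12, 1.0, w)
        else:
            raise ValueError(f"unknown method {method!r}")
    return w


def _expected_information(mu, stations, kappa):
    """Expected Fisher information of the location: kappa*A(kappa) * sum grad grad'."""
    dx = mu[0] - stations[:, 0]
    dy = mu[1] - stations[:, 1]
    d2 = dx * dx + dy * dy
    # gradient of theta_tilde wrt mu is (-dy, dx)/d^2
    gx = -dy / d2
    gy = dx / d2
    info = np.array(
        [[np.sum(gx * gx), np.sum(gx * gy)], [np.sum(gx * gy), np.sum(gy * gy)]]
    )
    return kappa * float(bessel_ratio(kappa)) * info


def _support_radius(stations):
    if len(stations) < 2:
        return 1.0
    span = np.linalg.norm(stations.max(axis=0) - stations.min(axis=0))
    return max(span, 1.0)


def _fixed_point(stations, bearings, method, tuning_c, init, tol, max_iter):
    """Lenth-style iteratively reweighted line intersection.

    Each pass recomputes the station->estimate geometry, the weights
    (1/d for the score scaling, times the robustness weight), and solves the
    2x2 weighted-intersection system whose fixed point zeroes the exact von
    Mises score.
    """
    s = np.sin(bearings)
    c = np.cos(bearings)
    mu = init.astype(float).copy()
    n = len(bearings)
    radius = _support_radius(stations)
    kappa_hat = None
    for it in range(1, max_iter + 1):
        dx = mu[0] - stations[:, 0]
        dy = mu[1] - stations[:, 1]
        d = np.hypot(dx, dy)
        if np.any(d < 1e-9):
            return mu, None, False, it, "estimate collapsed onto a station"
        st = dy / d  # sin(theta_tilde)
        ct = dx / d
        resid = wrap_angle(bearings - np.arctan2(dy, dx))
        rbar = mean_resultant_length(resid)
        kappa_hat = kappa_from_resultant(rbar)
        w = _psi_weights(resid * np.sqrt(max(kappa_hat, 1e-8)), method, tuning_c)
        # rows: sum w_i * (s~|c~)_i / d_i^2 * [s_i*(mu1 - x_i) - c_i*(mu2 - y_i)] = 0
        a1 = w * st / d**2
        a2 = w * ct / d**2
        rhs_terms = s * stations[:, 0] - c * stations[:, 1]
        A = np.array(
            [
                [np.sum(a1 * s), -np.sum(a1 * c)],
                [np.sum(a2 * s), -np.sum(a2 * c)],
            ]
        )
        b = np.array([np.sum(a1 * rhs_terms), np.sum(a2 * rhs_terms)])
        det = np.linalg.det(A)
        if not np.isfinite(det) or abs(det) < 1e-14 * max(np.abs(A).max() ** 2, 1e-30):
            return mu, kappa_hat, False, it, "singular 2x2 system (parallel azimuths)"
        new = np.linalg.solve(A, b)
        step = np.linalg.norm(new - mu)
        if not np.isfinite(step) or step > 10.0 * radius:
            return new, kappa_hat, False, it, "divergent update"
        mu = new
        if step < tol:
            return mu, kappa_hat, True, it, ""
    return mu, kappa_hat, False, max_iter, "max iterations reached"


def triangulate(
    azimuths,
    method: str = "mle-fixed-point",
    tuning_c: float = 1.5,
    init=None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> TriangulationFit:
    """Triangulate one animal location from >= 2 azimuths.

    Parameters
    ----------
    azimuths : sequence of (station, bearing) pairs
        Station is an (easting, northing) pair in meters; bearing is a math
        radian angle (see `azitel.circular`).
    method : one of ``METHODS``
    tuning_c : robustness tuning constant for Huber/Andrews.
    init : starting location; default is the intersection average.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    stations, bearings = _as_arrays(azimuths)
    n = len(bearings)
    if n < 2:
        raise ValueError("need at least 2 azimuths for a point estimate")

    if method == "intersection-average":
        p = intersection_average(azimuths)
        ok = p is not None
        return TriangulationFit(
            estimate=p, covariance=None, converged=ok, n_iterations=0,
            method=method, message="" if ok else "no azimuth intersections", n_azimuths=n,
        )

    mu0 = np.asarray(init, dtype=float) if init is not None else _default_init(stations, bearings)

    if method == "mle-quasi-newton":
        res = minimize(
            _objective, mu0, args=(stations, bearings), method="BFGS",
            options={"gtol": tol, "maxiter": max_iter},
        )
        mu, ok, nit, msg = res.x, bool(res.success), int(res.nit), res.message if not res.success else ""
        dx = mu[0] - stations[:, 0]
        dy = mu[1] - stations[:, 1]
        if np.any(np.hypot(dx, dy) < 1e-9):
            ok, msg = False, "estimate collapsed onto a station"
        resid = wrap_angle(bearings - np.arctan2(dy, dx)) if ok else None
        kappa_hat = kappa_from_resultant(mean_resultant_length(resid)) if ok else None
    else:
        mu, kappa_hat, ok, nit, msg = _fixed_point(
            stations, bearings, method, tuning_c, mu0, tol, max_iter
        )

    cov = None
    if ok and n >= 3 and kappa_hat is not None and kappa_hat > 0:
        info = _expected_information(mu, stations, kappa_hat)
        det = np.linalg.det(info)
        if np.isfinite(det) and det > 0:
            cov = np.linalg.inv(info)
            cov = 0.5 * (cov + cov.T)
    est = (float(mu[0]), float(mu[1])) if ok else None
    return TriangulationFit(
        estimate=est, covariance=cov, converged=ok, n_iterations=nit,
        method=method, kappa_hat=kappa_hat, message=msg, n_azimuths=n,
    )


def confidence_ellipse(fit: TriangulationFit, level: float = 0.95) -> ConfidenceEllipse:
    """Asymptotic-normal confidence ellipse {u : (u-mu)' Sigma^-1 (u-mu) <= chi2_2(level)}."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if not fit.converged or fit.covariance is None:
        raise ValueError("fit did not converge or has no covariance")
    cov = np.asarray(fit.covariance, dtype=float)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise ValueError("singular covariance")
    q = chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(q * evals)
    orient = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(
        center=fit.estimate, semi_axes=(float(semi[0]), float(semi[1])),
        orientation=orient, level=level, covariance=cov,
    )
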