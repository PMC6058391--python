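"""Circular geometry primitives shared by every estimator in the package.

Conventions (normative for the whole package):

* All internal angles are mathematical bearings: radians, counterclockwise
  from the +x axis (east), wrapped to ``(-pi, pi]``.
* Field azimuths arrive as compass degrees (clockwise from north) and are
  converted at I/O time via ``rad = wrap(pi/2 - deg * pi / 180)``.
* Coordinates are planar eastings/northings in meters; no geodesy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "wrap_angle",
    "compass_deg_to_math_rad",
    "math_rad_to_compass_deg",
    "expected_bearing",
    "vonmises_logpdf",
    "vonmises_sample",
    "mean_resultant_length",
    "kappa_from_resultant",
    "ray_intersection",
    "VonMisesParams",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction (radians) and concentration kappa (dimensionless, >= 0)."""

    mean_direction: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_direction):
            raise ValueError("mean direction must be finite")
        if not (self.kappa >= 0):
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("angle must be finite")
    wrapped = theta - _TWO_PI * np.floor((theta + np.pi) / _TWO_PI)
    # floor maps pi -> -pi; put the boundary back on +pi
    wrapped = np.where(wrapped <= -np.pi, np.pi, wrapped)
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


def compass_deg_to_math_rad(deg):
    """Compass azimuth (degrees clockwise from north) -> math bearing (radians)."""
    deg = np.asarray(deg, dtype=float)
    if not np.all(np.isfinite(deg)):
        raise ValueError("azimuth must be finite")
    return wrap_angle(np.pi / 2.0 - np.deg2rad(deg))


def math_rad_to_compass_deg(rad):
    """Math bearing (radians) -> compass azimuth in [0, 360) degrees."""
    rad = np.asarray(rad, dtype=float)
    if not np.all(np.isfinite(rad)):
        raise ValueError("bearing must be finite")
    deg = np.rad2deg(np.pi / 2.0 - rad) % 360.0
    if np.ndim(rad) == 0:
        return float(deg)
    return deg


def expected_bearing(mu, z):
    """Direction from station ``z`` toward animal location ``mu``.

    Quadrant-aware inverse tangent of the displacement vector; both arguments
    are ``(x, y)`` pairs or arrays of shape ``(..., 2)``.
    """
    mu = np.asarray(mu, dtype=float)
    z = np.asarray(z, dtype=float)
    dx = mu[..., 0] - z[..., 0]
    dy = mu[..., 1] - z[..., 1]
    if np.any((dx == 0) & (dy == 0)):
        raise ValueError("station coincides with the animal location (distance 0)")
    out = np.arctan2(dy, dx)
    if out.ndim == 0:
        return float(out)
    return out


def _log_i0(kappa):
    # log I0(k) computed stably through the exponentially scaled Bessel function
    return np.log(i0e(kappa)) + kappa


def vonmises_logpdf(theta, mean_direction, kappa):
    """Von Mises log density: ``kappa*cos(theta - mu) - log(2*pi*I0(kappa))``.

    ``kappa = 0`` reduces to the circular uniform density ``1/(2*pi)``.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    theta = np.asarray(theta, dtype=float)
    out = kappa * np.cos(theta - mean_direction) - np.log(_TWO_PI) - _log_i0(kappa)
    if out.ndim == 0:
        return float(out)
    return out


def vonmises_sample(mean_direction, kappa, rng, size=None):
    """Draw von Mises bearings, wrapped to (-pi, pi]. ``kappa=0`` is uniform."""
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    draws = rng.vonmises(mean_direction, kappa, size=size)
    return wrap_angle(draws)


def mean_resultant_length(angles):
    """Mean resultant length R-bar of a sample of angles."""
    angles = np.asarray(angles, dtype=float)
    return float(np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles))))


def bessel_ratio(kappa):
    """A(kappa) = I1(kappa)/I0(kappa), the expected resultant length."""
    kappa = np.asarray(kappa, dtype=float)
    return i1e(kappa) / i0e(kappa)


def kappa_from_resultant(rbar: float) -> float:
    """Invert A(kappa) = rbar by the standard piecewise approximation (Fisher 1993)."""
    rbar = min(max(float(rbar), 0.0), 1.0 - 1e-12)
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def ray_intersection(z1, b1, z2, b2, rays: bool = True):
    """Intersection of two bearings taken at stations ``z1`` and ``z2``.

    With ``rays=True`` (default) the crossing must lie forward along *both*
    bearings — a bearing points toward the animal, so backward extensions are
    not admissible. Returns ``None`` for parallel/antiparallel bearings or
    when the crossing lies behind either station; ``rays=False`` gives the
    infinite-line intersection.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.all(z1 == z2):
        raise ValueError("coincident stations")
    d1 = np.array([np.cos(b1), np.sin(b1)])
    d2 = np.array([np.cos(b2), np.sin(b2)])
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-12:
        return None
    dz = z2 - z1
    t1 = (dz[0] * d2[1] - dz[1] * d2[0]) / denom
    t2 = (dz[0] * d1[1] - dz[1] * d1[0]) / denom
    if rays and (t1 <= 0.0 or t2 <= 0.0):
        return None
    p = z1 + t1 * d1
    return (float(p[0]), float(p[1]))
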