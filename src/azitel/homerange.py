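"""Home-range estimation with propagated location uncertainty.

The utilization distribution (UD) is a fixed-bandwidth Gaussian product
kernel over an individual's relocations::

    f(c) = (1 / (n b^2)) * sum_i g((c1 - mu_1i)/b) g((c2 - mu_2i)/b)

with a single bandwidth ``b`` shared by both coordinates. The 95% home
range is the smallest-area region enclosing 95% of UD mass (a grid
threshold rule); a convex hull is the non-parametric alternative.

When locations come from an ATM posterior, the home range is a *derived
quantity*: for each retained MCMC iteration k the UD/hull is recomputed
from that iteration's joint location draw, yielding a posterior
distribution of isopleth shape and area. The bandwidth is computed once
from the posterior-median locations and held fixed across iterations so
that area variation reflects location uncertainty only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from skimage import measure

__all__ = [
    "HomeRangeSpec",
    "HomeRangeResult",
    "HomeRangePosterior",
    "kernel_ud",
    "isopleth_and_hull",
    "home_range_posterior",
    "silverman_bandwidth",
]


@dataclass
class HomeRangeSpec:
    bandwidth: float | None = None  # meters; None -> Silverman reference rule
    level: float = 0.95
    grid_resolution: float | None = None  # meters; None -> 1/200 of bbox diagonal
    n_grid_pad: float = 3.5  # bandwidths of padding around the points


@dataclass
class UDSurface:
    xs: np.ndarray
    ys: np.ndarray
    density: np.ndarray  # (len(ys), len(xs)), row y-major
    resolution: float
    bandwidth: float

    def mass(self) -> float:
        return float(self.density.sum() * self.resolution**2)


@dataclass
class HomeRangeResult:
    isopleth: MultiPolygon | Polygon | None
    isopleth_area: float
    hull: Polygon
    hull_area: float
    level: float
    bandwidth: float


@dataclass
class HomeRangePosterior:
    results: list  # HomeRangeResult per sampled iteration
    plugin: HomeRangeResult | None  # from fixed point estimates, uncertainty ignored
    spec: HomeRangeSpec
    bandwidth: float = 0.0

    @property
    def isopleth_areas(self) -> np.ndarray:
        return np.asarray([r.isopleth_area for r in self.results])

    @property
    def hull_areas(self) -> np.ndarray:
        return np.asarray([r.hull_area for r in self.results])

    def area_summary(self, which: str = "isopleth") -> dict:
        a = self.isopleth_areas if which == "isopleth" else self.hull_areas
        lo, hi = np.percentile(a, [2.5, 97.5])
        return {"median": float(np.median(a)), "ci95": (float(lo), float(hi))}


def silverman_bandwidth(points: np.ndarray) -> float:
    """Bivariate normal-reference bandwidth with a common b for both axes."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n < 2:
        return 1.0
    sd = np.sqrt(0.5 * (points[:, 0].var(ddof=1) + points[:, 1].var(ddof=1)))
    return float(max(sd, 1e-9) * n ** (-1.0 / 6.0))


def kernel_ud(points, spec: HomeRangeSpec | None = None, grid=None) -> UDSurface:
    """Evaluate the fixed-bandwidth Gaussian UD on a regular grid.

    ``grid`` may be a precomputed ``(xs, ys)`` pair; otherwise a grid padded
    by ``spec.n_grid_pad`` bandwidths around the points is built.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("no points")
    spec = spec or HomeRangeSpec()
    b = spec.bandwidth if spec.bandwidth is not None else silverman_bandwidth(points)
    if not (b > 0):
        raise ValueError("bandwidth must be > 0")
    if grid is None:
        pad = spec.n_grid_pad * b
        x0, y0 = points.min(axis=0) - pad
        x1, y1 = points.max(axis=0) + pad
        res = spec.grid_resolution or max(np.hypot(x1 - x0, y1 - y0) / 200.0, 1e-9)
        xs = np.arange(x0, x1 + res, res)
        ys = np.arange(y0, y1 + res, res)
    else:
        xs, ys = (np.asarray(g, dtype=float) for g in grid)
        res = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    # separable product kernel: (n_y, n_pts) x (n_pts, n_x) contraction
    gx = np.exp(-((xs[None, :] - points[:, 0][:, None]) ** 2) / (2 * b * b))
    gy = np.exp(-((ys[None, :] - points[:, 1][:, None]) ** 2) / (2 * b * b))
    dens = (gy.T @ gx) / (len(points) * 2 * np.pi * b * b)
    return UDSurface(xs=xs, ys=ys, density=dens, resolution=res, bandwidth=b)


def _mass_threshold(density: np.ndarray, res: float, level: float) -> float:
    """Density threshold whose super-level set holds `level` of total UD mass."""
    flat = np.sort(density.ravel())[::-1]
    csum = np.cumsum(flat) * res * res
    total = csum[-1]
    idx = int(np.searchsorted(csum, level * total))
    idx = min(idx, len(flat) - 1)
    return float(flat[idx])


def _contours_to_polygons(surface: UDSurface, threshold: float):
    dens = surface.density
    x0, y0 = surface.xs[0], surface.ys[0]
    res = surface.resolution
    polys = []
    for contour in measure.find_contours(dens, threshold):
        # contour rows are (row=y index, col=x index)
        xy = np.column_stack([x0 + contour[:, 1] * res, y0 + contour[:, 0] * res])
        if len(xy) >= 4:
            poly = Polygon(xy)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    if not polys:
        return None
    # nest holes: subtract any polygon contained in another
    polys.sort(key=lambda p: p.area, reverse=True)
    outer = []
    for p in polys:
        hole_of = next((o for o in outer if o.contains(p)), None)
        if hole_of is None:
            outer.append(p)
        else:
            outer[outer.index(hole_of)] = hole_of.difference(p)
    merged = outer[0] if len(outer) == 1 else MultiPolygon(outer).buffer(0)
    return merged


def isopleth_and_hull(points_or_surface, level: float = 0.95,
                      spec: HomeRangeSpec | None = None) -> HomeRangeResult:
    """Home-range isopleth and convex hull of one location set (or UD surface).

    The isopleth area is counted on the grid (cells above the mass
    threshold); the polygon outline comes from marching squares and may be
    multi-part when the UD is not contiguous.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if isinstance(points_or_surface, UDSurface):
        surface = points_or_surface
        pts = None
    else:
        pts = np.atleast_2d(np.asarray(points_or_surface, dtype=float))
        spec = spec or HomeRangeSpec()
        surface = kernel_ud(pts, spec)
    thr = _mass_threshold(surface.density, surface.resolution, level)
    area = float(np.count_nonzero(surface.density >= thr) * surface.resolution**2)
    poly = _contours_to_polygons(surface, thr)
    if pts is None:
        hull = Polygon()
    else:
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if hull.geom_type != "Polygon":
            hull = hull.buffer(0) if hull.area > 0 else Polygon()
    return HomeRangeResult(
        isopleth=poly, isopleth_area=area, hull=hull,
        hull_area=float(hull.area), level=level, bandwidth=surface.bandwidth,
    )


def home_range_posterior(atm_posterior, spec: HomeRangeSpec | None = None,
                         n_mc: int = 500, plugin_points=None) -> HomeRangePosterior:
    """Posterior distribution of home-range shape and area.

    ``atm_posterior`` is an :class:`azitel.atm.ATMPosterior` whose relocations
    all share a chain (same number of retained draws). For each of ``n_mc``
    equally spaced iterations the joint location draw is assembled and the
    UD isopleth and convex hull recomputed. ``plugin_points`` (e.g. Lenth MLE
    point estimates) yields the uncertainty-ignored comparison estimate.
    """
    spec = spec or HomeRangeSpec()
    ids, draws = atm_posterior.location_draw_matrix()  # (n_draws, K, 2)
    n_draws = draws.shape[0]
    if n_draws == 0:
        raise ValueError("empty posterior")
    medians = np.median(draws, axis=0)
    b = spec.bandwidth if spec.bandwidth is not None else silverman_bandwidth(medians)
    fixed_spec = HomeRangeSpec(bandwidth=b, level=spec.level,
                               grid_resolution=spec.grid_resolution)
    idx = np.unique(np.linspace(0, n_draws - 1, min(n_mc, n_draws)).astype(int))
    results = [isopleth_and_hull(draws[i], spec.level, fixed_spec) for i in idx]
    plugin = None
    if plugin_points is not None:
        plugin = isopleth_and_hull(np.asarray(plugin_points, float), spec.level, fixed_spec)
    return HomeRangePosterior(results=results, plugin=plugin, spec=fixed_spec, bandwidth=b)
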