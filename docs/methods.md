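# Methods

This note records the models implemented in `azitel`, the defaults and
numerical choices that matter, what the synthetic-data generators do and do
not emulate, and known limitations.

## Observation model and conventions

A recorded azimuth is modeled as von Mises about the true station-to-animal
bearing with concentration κ; the link is the quadrant-aware inverse tangent
of the displacement vector. All internal angles are mathematical bearings
(radians, counterclockwise from east, wrapped to (−π, π]); compass azimuths
(degrees clockwise from north) are converted at I/O time via
`rad = wrap(π/2 − deg·π/180)`. Coordinates are projected planar meters
throughout — no geodesy. κ is treated as dimensionless.

## Classical estimators

The Lenth-style MLE minimizes `Σ (1 − cos(θ_i − θ̃_i(μ)))` by an iteratively
reweighted line-intersection scheme: each pass freezes the unit direction and
distance from the current estimate to every station and solves the resulting
2×2 linear system. At a fixed point the exact von Mises score is zero, which
is verified in tests by finite-difference gradients and grid search rather
than by numerical identity with any legacy implementation (whose exact
iteration constants are not public). M-estimators multiply the weights by
ψ(t)/t — Huber `ψ(t) = clamp(t, ±c)` or Andrews `ψ(t) = sin(t/c)·1{|t| ≤ cπ}`
— with standardized residuals `t = resid·√κ̂`, κ̂ re-estimated each pass from
the mean resultant length of residuals via the standard inverse-A(κ)
approximation. The tuning constant defaults to c = 1.5.

Convergence is declared when the update moves < 1e−6 m (max 100 passes);
divergence when a step exceeds 10× the station-span. Failures (parallel
azimuths, singular systems, divergence) return a structured non-result so
benchmarks can count success rates. A quasi-Newton (BFGS) fit of the same
objective is provided because some software fits this model that way; it is
allowed to fail more often. Covariances come from the inverse expected
information `κ̂ A(κ̂) Σ ∇θ̃ ∇θ̃'`; with only two azimuths a point estimate is
returned but no covariance. Confidence ellipses are
`{u : (u−μ̂)'Σ⁻¹(u−μ̂) ≤ χ²₂(level)}`.

## The ATM sampler

The location prior is uniform over the union of circles of radius r around
the relocation's stations; r is the maximum distance at which the animal
could be detected and must be supplied (a data-driven helper — 3× the 95th
percentile of pairwise station spacing — exists, but a detection-based value
is strongly preferable; see "Sensitivity to r"). Two concentration models
are available:

* **hierarchical** (default): per-azimuth `log κ ~ N(w'β + α₁ log d, σ²_κ)`
  with conjugate normal/inverse-gamma updates for β and σ²_κ and
  random-walk updates for each log κ and for α₁ (the distance d is
  recomputed from the current location draw every sweep). Hyperpriors:
  μ_β = 0, Σ_β = diag(4); σ²_κ ~ IG(2, 1); α₁ ~ N(0, 4).
* **homogeneous** (`KappaModel(homogeneous=True)`): one shared κ for all
  azimuths, prior `log κ ~ N(0, 4)`, scalar random walk. This is the mode
  used by the simulation benchmark, where all azimuths share one true κ.

Locations get per-relocation Gaussian random-walk proposals, rejected
outside the support (the uniform prior enforced as an indicator). Proposal
scales adapt every 50 iterations during burn-in toward acceptance rates of
roughly 0.2–0.45 and are then frozen, so a fixed seed reproduces the chain
bit-for-bit. Defaults: burn-in 20% of iterations, no thinning, location
proposal scale r/10, log κ scale 0.5. log κ is clamped to [−10, 20] to keep
the Bessel terms finite. Stations exactly at the animal (distance 0) are
rejected at ingest.

The sampler was validated two ways: single-azimuth posteriors agree with
direct rejection sampling of the unnormalized posterior
(Kolmogorov–Smirnov on both marginals), and the shared-κ marginal agrees
with brute-force 2-D grid integration of the integrated likelihood.

## HPD isopleths

Uncertainty regions are highest-density regions of a Gaussian-product KDE of
the location draws, bandwidth by the bivariate normal-reference rule
`b = sd·n^(−1/6)`. The threshold is the largest density value such that the
fraction of draws with density ≥ threshold reaches the level, so the
enclosed posterior mass is measured on the draws themselves; `contains`
evaluates the KDE at a point against that threshold. Regions are nested
across levels by construction. Degenerate (zero-spread) posteriors collapse
to a point region with containment at grid resolution. Area is counted on a
grid (default 1/200 of the bounding-box diagonal) clipped to the support.

## Study-design simulators

Truth locations are scattered over a nominal 100 km study square; observers
are placed per design: *random* — independent uniform bearings; *encircle* —
first bearing uniform, each subsequent bearing advanced counterclockwise by
U(30°, 60°); *road* — stations on a random line whose offset from the animal
is one distance draw, spaced uniformly within ±1 offset along it. Distances
are re-drawn per observer from the distance sampler, default Uniform(100 m,
1000 m) — a stand-in for field-measured detection distances, which makes
absolute errors meaningful only in the sampler's own units. Azimuths are von
Mises draws about the true bearings.

The benchmark fits every estimator to the same azimuths and records the
number of successes, the median Euclidean error over successes, and 95%
region coverage of the truth (denominator: fits that produced a region). The
ATM is fit jointly per scenario in homogeneous-κ mode with r = 1000 m — the
generative maximum detection distance. Desk-scale defaults (100–150
relocations per scenario, 8,000 iterations) keep a full sweep within minutes
on one CPU; the package's own reduced problem sizes, chosen once.

### Sensitivity to r, and what calibration to expect

The marginal posterior of a shared κ depends strongly on r: the uniform
support contributes likelihood volume, and when r is large relative to
typical observer–animal distances the integrated likelihood favors smaller κ
(verified against exact grid integration: with true log κ = 3.22 and
distances U(100, 1000), the posterior mode is ≈3.0 at r = 1000 but ≈1.9 at
r = 1500 and ≈1.2 at r = 3000). Set r to the real maximum detection
distance, not a generous multiple of it.

With r chosen that way, the ATM's 95% HPD isopleths cover the true location
at close to the nominal rate (≈0.95 on average across designs here; the
exact-likelihood HPD with known κ gives 0.950–0.957 under the same
geometries, so near-nominal is the theoretically expected behavior of a
calibrated region under these conditions). Classical 95% ellipses cover at
roughly 0.23–0.57 on the same data. Published azimuthal-telemetry
simulations report ATM-style coverage somewhat below nominal (≈0.82–0.92)
and a 1.5–2.5× accuracy gain from a fourth azimuth; with the designs and
the uniform distance stand-in implemented here the accuracy gain is a more
modest ≈1.2–1.4× (close to the √(4/3) information bound plus the geometry
gain), and coverage sits at nominal rather than slightly below it.

## Home range

The utilization distribution is a product Gaussian kernel with one bandwidth
b for both axes. For posterior home ranges, b is computed once from the
posterior-median locations (normal-reference rule) and held fixed across
iterations so that area variation reflects location uncertainty only, and
the isopleth is the smallest grid region holding the target UD mass
(multi-part allowed; marching-squares outlines). The per-iteration convex
hull is the non-parametric alternative. 500 equally spaced iterations by
default. The plug-in estimate from fixed point estimates (e.g. Lenth MLE
medians) gives the uncertainty-ignored comparison.

## Resource selection

The RSF is a weighted (inhomogeneous point process) distribution over a
uniform availability region — the full raster or a convex hull of locations;
the availability-coefficient slot of the general formulation is carried but
never estimated. The normalizing integral is a midpoint cell sum at raster
resolution, exact for the piecewise-constant covariates. Continuous
covariates are centered/scaled over the availability region (coefficients
are on the standardized scale); 0/1 layers are left alone. No intercept is
included — it is not identifiable in the normalized form.

Individual coefficients get random-walk Metropolis updates against the exact
log likelihood; with ≥2 individuals the population mean and covariance get
conjugate normal and Wishart updates (μ_0 = 0, Σ_0 = diag(100),
ν = dim(γ)+1, S = I); a single individual is fit against the N(μ_0, Σ_0)
prior directly. In the joint ATM-RSF, the selection surface replaces the
uniform location prior inside (support ∩ availability): location proposals
are weighted by exp(x'(μ)γ) and γ is refreshed each sweep from the current
location draws. The availability region is fixed (not recomputed per
iteration) to keep the normalizer stable. Fixing γ = 0 reduces the joint
model exactly to the plain ATM restricted to availability.

Covariate landscapes for simulation are zero-mean unit-variance Gaussian
random fields with exponential covariance, generated by FFT circulant
embedding (negative embedding eigenvalues clipped, field rescaled); the
low/moderate/high autocorrelation settings map to ranges of 2/8/32 cells.
The categorical layer is an independent field thresholded at its median.

## What the generators do not emulate

Real azimuthal data contain signal bounce (terrain-deflected bearings that
are outliers, not von Mises noise), observer-specific and time-varying
precision, animal movement between the first and last azimuth of a
relocation, and empirically skewed detection-distance distributions. None of
these are simulated, so passing benchmarks here demonstrate correctness of
the estimators under the stated model, not robustness to those field
realities. Rasters are ESRI ASCII grids only; geographic (lat/lon) input,
movement-process models, and outlier-identification extensions are out of
scope.
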