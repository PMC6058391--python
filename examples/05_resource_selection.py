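"""Resource selection with and without location uncertainty.

Simulates a Gaussian-random-field covariate landscape and point-process use
locations with known selection coefficients, observes each location only
through three noisy azimuths, and compares three RSF fits: true locations,
Lenth point estimates (uncertainty ignored), and the joint ATM-RSF.
"""

import numpy as np
import pandas as pd

from azitel.atm import MCMCConfig
from azitel.circular import expected_bearing, vonmises_sample
from azitel.classical import triangulate
from azitel.designs import DesignScenario, generate_design, simulate_relocation
from azitel.rsf import Availability, fit_atm_rsf, fit_rsf, sample_ipp_locations, simulate_grf_covariates

rng = np.random.default_rng(12)
raster = simulate_grf_covariates(40, 40, 25.0, "low", rng)  # 1 km x 1 km
availability = Availability(raster)
gamma_true = np.array([1.0, 1.0])  # continuous, categorical selection

truths = sample_ipp_locations(gamma_true, availability, 100, rng)
scenario = DesignScenario(design="random", n_theta=3, kappa_true=50.0,
                          distance_sampler=lambda r, size=None: r.uniform(100, 400, size))
frames, lenth = [], []
for i, t in enumerate(truths):
    stations = generate_design(t, scenario, rng)
    df = simulate_relocation(t, stations, 50.0, rng)
    df.insert(0, "relocation", i)
    frames.append(df)
    fit = triangulate(list(zip(stations, df["bearing"])))
    if fit.converged:
        lenth.append(fit.estimate)
observations = pd.concat(frames, ignore_index=True)

x0, y0, x1, y1 = raster.bounds()
lenth = np.array([p for p in lenth if x0 <= p[0] < x1 and y0 <= p[1] < y1])

fits = {
    "true locations": fit_rsf(truths, availability, mcmc=MCMCConfig(n_iter=4000, seed=1)),
    "Lenth (no uncertainty)": fit_rsf(lenth, availability,
                                      mcmc=MCMCConfig(n_iter=4000, seed=2)),
}
_, atm_rsf = fit_atm_rsf(observations, availability, radius_r=600.0,
                         mcmc=MCMCConfig(n_iter=8000, seed=3))
fits["ATM-RSF (joint)"] = atm_rsf

print(f"true gamma = {gamma_true}\n")
for name, post in fits.items():
    summ = post.gamma_summary(0)
    line = ", ".join(f"{r.coef}: {r['median']:+.2f} [{r.lo95:+.2f}, {r.hi95:+.2f}]"
                     for _, r in summ.iterrows())
    print(f"{name:24s} {line}")
print("\nWith a heterogeneous (low-autocorrelation) covariate, plugging in")
print("point estimates attenuates the selection coefficients toward zero;")
print("propagating location uncertainty through the joint model recovers")
print("estimates close to the true-location fit.")
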