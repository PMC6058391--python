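"""Fit the Bayesian azimuthal telemetry model (ATM) to simulated bearings.

Simulates 20 relocations under the encircle design (3 azimuths each,
kappa=50), fits the ATM jointly with a shared kappa, and reports the
concentration posterior, location accuracy, and 95% HPD coverage.
"""

import numpy as np

from azitel.atm import KappaModel, MCMCConfig, fit_atm, hpd_isopleth
from azitel.designs import DesignScenario, simulate_scenario

scenario = DesignScenario(design="encircle", n_theta=3, kappa_true=50.0,
                          n_locations=20, seed=5)
observations, truths = simulate_scenario(scenario)

posterior = fit_atm(
    observations,
    KappaModel(homogeneous=True),
    radius_r=1000.0,  # maximum detection distance (defines the location prior)
    mcmc=MCMCConfig(n_iter=8000, seed=6),
)

log_kappa = posterior.beta[:, 0]
print(f"shared kappa posterior: median {np.exp(np.median(log_kappa)):.1f} "
      f"(truth {scenario.kappa_true})")

errors, covered = [], 0
for rid, loc in posterior.locations.items():
    med = loc.median
    errors.append(np.hypot(med[0] - truths[rid][0], med[1] - truths[rid][1]))
    region = hpd_isopleth(loc, 0.95)
    covered += region.contains(truths[rid])

print(f"median location error : {np.median(errors):.1f} m")
print(f"95% HPD coverage      : {covered}/{len(truths)} relocations")
print("\nEvery relocation gets a full posterior (even single or non-")
print("intersecting azimuths); coverage near 19/20 shows the calibrated")
print("uncertainty that classical ellipses lack.")
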