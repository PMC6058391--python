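"""Compare estimators across observer-placement designs (reduced scale).

Runs the coverage/accuracy benchmark on two small scenarios: for each, the
intersection average, Lenth MLE (with 95% ellipses) and the ATM (with 95%
HPD isopleths) are fit to the same simulated azimuths.
"""

from azitel.atm import MCMCConfig
from azitel.designs import DesignScenario, run_benchmark

scenarios = [
    DesignScenario(design="encircle", n_theta=3, kappa_true=100.0,
                   n_locations=40, seed=1),
    DesignScenario(design="road", n_theta=3, kappa_true=100.0,
                   n_locations=40, seed=2),
]
table = run_benchmark(scenarios,
                      estimators=("intersection-average", "mle-fixed-point"),
                      mcmc=MCMCConfig(n_iter=6000, seed=3), radius_r=1000.0)
print(table.to_string(index=False))
print("\nn_hat counts successful fits (the ATM always succeeds); d_median is")
print("the median error in meters; coverage is the fraction of 95% regions")
print("containing the truth — near nominal for the ATM, far below for the")
print("ellipses. The road design, with little angular diversity, is least")
print("accurate.")
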