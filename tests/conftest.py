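import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def benchmark_results():
    """Shared reduced-scale Table-1-style benchmark over the four headline
    scenarios (session-scoped: several acceptance checks read it)."""
    from azitel.atm import MCMCConfig
    from azitel.designs import DesignScenario, run_benchmark

    scenarios = [
        DesignScenario(design="encircle", n_theta=3, kappa_true=100.0,
                       n_locations=150, seed=101),
        DesignScenario(design="encircle", n_theta=3, kappa_true=25.0,
                       n_locations=150, seed=102),
        DesignScenario(design="encircle", n_theta=4, kappa_true=100.0,
                       n_locations=150, seed=103),
        DesignScenario(design="road", n_theta=3, kappa_true=25.0,
                       n_locations=150, seed=104),
    ]
    return run_benchmark(
        scenarios,
        estimators=("intersection-average", "mle-fixed-point"),
        mcmc=MCMCConfig(n_iter=8000, seed=105),
        radius_r=1000.0,
    )
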