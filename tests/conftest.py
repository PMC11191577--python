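import logging

import numpy as np
import pytest

import lymphmm as lm

logging.disable(logging.WARNING)  # chain-length advisories clutter test output


@pytest.fixture(scope="session")
def default_graph():
    return lm.build_default_graph()


@pytest.fixture(scope="session")
def obs_model():
    return lm.ObservationModel()  # MRI: sensitivity 0.81, specificity 0.63


@pytest.fixture(scope="session")
def time_config():
    return lm.TimeConfig()  # t_max 10, p_early 0.3


@pytest.fixture(scope="session")
def theta_star():
    return lm.default_generator_theta()


@pytest.fixture(scope="session")
def two_level_graph():
    return lm.LymphGraph(
        levels=("A", "B"),
        tumor_arcs=(("A", "bA"), ("B", "bB")),
        level_arcs=(("A", "B", "tAB"),),
    )


def random_theta(graph, rng, low=0.0, high=1.0):
    n = graph.n_levels + len(graph.level_arcs) + 1
    return lm.ParameterVector.from_array(graph, rng.uniform(low, high, n))


@pytest.fixture(scope="session")
def recovery_fit(default_graph, obs_model, time_config, theta_star):
    """The parameter-recovery experiment: 2000 patients (1000 early / 1000
    late) simulated at the generating parameters, posterior sampled by MCMC.

    Session-scoped because several risk and inference properties are
    checked against the same fit.
    """
    cohort = lm.simulate_cohort(theta_star, 1000, 1000, seed=1)
    samples = lm.sample_posterior(
        cohort,
        default_graph,
        obs_model,
        time_config,
        seed=1,
        sampler_config=lm.SamplerConfig(walkers=32, steps=4000, burn_in=1000),
    )
    return cohort, samples
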