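import pytest

import tsdfit as tf


@pytest.fixture(scope="session")
def table1_raw():
    return tf.table1_fixture()


@pytest.fixture(scope="session")
def table1(table1_raw):
    """Table of the 40 olive ridley incubation groups, intersexes excluded."""
    return tf.filter_dataset(table1_raw)


@pytest.fixture(scope="session")
def east_pacific(table1):
    return table1.subset(rmu="East Pacific")


@pytest.fixture(scope="session")
def costa_rica(table1):
    return table1.subset(country="Costa Rica")


@pytest.fixture(scope="session")
def global_logistic(table1):
    return tf.fit_mle(table1, "logistic")


@pytest.fixture(scope="session")
def global_flexit(table1):
    return tf.fit_mle(table1, "flexit")


@pytest.fixture(scope="session")
def ep_logistic(east_pacific):
    return tf.fit_mle(east_pacific, "logistic")


@pytest.fixture(scope="session")
def ep_draws(ep_logistic):
    return tf.resample_parameters(ep_logistic, n=10_000, seed=20260921)


@pytest.fixture(scope="session")
def ep_mcmc(east_pacific, ep_logistic):
    priors = tf.default_priors("logistic", ep_logistic)
    return tf.mh_mcmc(
        east_pacific, "logistic", priors, n_iter=100_000, seed=20260921, burn_in=10_000
    )
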