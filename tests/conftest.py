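import warnings

import pytest

from platekin.protocol import ProtocolSpec
from platekin.synthetic_cohort import (default_generator_constants,
                                       make_donor_stream)
from platekin.trace_processing import FeatureVector


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def gen_constants():
    return default_generator_constants()


@pytest.fixture(scope="session")
def healthy_features():
    return FeatureVector(ca_basal_nM=8.0, ca_max_nM=91.0,
                         fib_rel=0.16, ssc_change=0.31)


@pytest.fixture(scope="session")
def noiseless_stream(protocol, healthy_features):
    """A healthy donor without event noise (fast, 200 events/s)."""
    return make_donor_stream(healthy_features, protocol, seed=0,
                             event_rate=200.0, noise_cv=0.0)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Calibration clipping and small-cohort warnings are routine here."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
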