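import numpy as np
import pytest

from pcgseg.pipeline import prepare_example, train_segmenter
from pcgseg.synthetic import SimConfig, simulate_pcg


@pytest.fixture(scope="session")
def segmenter():
    """Frame classifier trained once on 200 simulated recordings.

    Shared by every test that needs realistic posteriors; the training set
    seed differs from all held-out evaluation seeds used in the tests.
    """
    return train_segmenter(n_train=200, seed=7, epochs=12)


@pytest.fixture(scope="session")
def normal_example():
    """One murmur-free recording with features and frame labels."""
    cfg = SimConfig(heart_rate_bpm=90.0, murmur="none", seed=11)
    rec, intervals = simulate_pcg(cfg)
    sf, fl = prepare_example(rec, intervals)
    return rec, intervals, sf, fl


@pytest.fixture(scope="session")
def murmur_example():
    """One loud holosystolic-murmur recording with features and frame labels."""
    cfg = SimConfig(heart_rate_bpm=90.0, murmur="holo", murmur_snr_db=0.0, seed=12)
    rec, intervals = simulate_pcg(cfg)
    sf, fl = prepare_example(rec, intervals)
    return rec, intervals, sf, fl


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
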