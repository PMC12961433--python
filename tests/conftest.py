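import numpy as np
import pytest

import rcbind as rb


@pytest.fixture(scope="session")
def truth():
    """Default ground-truth energy model (consensus TGATTTAT)."""
    return rb.GroundTruthAffinityModel.from_consensus(seed=0)


@pytest.fixture(scope="session")
def small_sim(truth):
    """A small simulated affinity table shared by unit tests."""
    return rb.simulate_dataset(truth, rb.SimConfig(n_reads=3000, seed=7))


@pytest.fixture(scope="session")
def tiny_rc_model(small_sim):
    """A quickly trained RC-tied CNN for interpretation tests."""
    cfg = rb.CnnConfig(variant="rc_shared", n_filters=8, epochs=6, seed=7)
    model, _ = rb.train_cnn(small_sim, cfg)
    return model


class TruthHandle:
    """Adapter exposing a ground-truth model through the predict interface."""

    def __init__(self, truth, input_length=14):
        self.truth = truth
        self.input_length = input_length

    def predict(self, sequences):
        return np.array([self.truth.true_affinity(s) for s in sequences])


@pytest.fixture(scope="session")
def truth_handle(truth):
    return TruthHandle(truth)
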