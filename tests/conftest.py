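import numpy as np
import pytest

from timpdesign import (
    HyperParams,
    ReferenceScheme,
    TrainingExample,
    train_ensemble,
)
from timpdesign.synthetic import make_reference_scheme


@pytest.fixture(scope="session")
def scheme() -> ReferenceScheme:
    """Synthetic full-size reference scheme (7 positions, 20 letters)."""
    return make_reference_scheme()


@pytest.fixture(scope="session")
def reduced_scheme() -> ReferenceScheme:
    """Tiny scheme for brute-force oracles: 3 positions, 4-letter alphabet."""
    return ReferenceScheme(
        wt_sequence="ACD", targeted_positions=(1, 2, 3), alphabet=("A", "C", "D", "W")
    )


class ToyModel:
    """Duck-typed stand-in for an ensemble: deterministic score function."""

    def __init__(self, scheme, score_fn):
        self.scheme = scheme
        self._score = score_fn

    def predict_signatures(self, signatures, chunk=None):
        return np.array([self._score(s) for s in signatures], dtype=np.float64)


@pytest.fixture(scope="session")
def toy_model_factory():
    return ToyModel


@pytest.fixture(scope="session")
def small_trained_ensemble(reduced_scheme):
    """A genuinely trained (tiny) ensemble on a planted additive task."""
    rng = np.random.default_rng(7)
    sigs = ["".join(s) for s in __import__("itertools").product("ACDW", repeat=3)]
    labels = {s: s.count("W") * 1.0 - s.count("D") * 0.5 for s in sigs}
    examples = [
        TrainingExample(signature=s, label=labels[s], weight_raw=int(rng.integers(4, 200)))
        for s in sigs
    ]
    hp = HyperParams(batch_size=8, epochs=200, learning_rate=1e-2, architecture="Lib")
    model = train_ensemble(examples, hp, reduced_scheme, n_members=3)
    return model, examples, labels
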