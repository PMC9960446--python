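import numpy as np
import pytest

from caensembles.ensembles import ClassifierConfig, classify_population
from caensembles.synthetic import NeuronSpec, SessionConfig, simulate_session

#: planted population used by recovery-style tests: 10 neurons per ON subtype
#: (amplitude 5 in noise-SD units), 40 untuned.
PLANTED_CLASSES = (
    ["Trigger-like"] * 10
    + ["Attention-like"] * 10
    + ["Reward-pursuing"] * 10
    + ["Rewarded"] * 10
    + ["Other"] * 40
)


@pytest.fixture(scope="session")
def planted_session():
    config = SessionConfig(n_trials=100, seed=11)
    specs = [
        NeuronSpec(tuning_class=c, response_amplitude=5.0 if c != "Other" else 0.0)
        for c in PLANTED_CLASSES
    ]
    bundle, truth = simulate_session(config, specs)
    return bundle, truth


@pytest.fixture(scope="session")
def planted_labels(planted_session):
    bundle, _ = planted_session
    return classify_population(
        bundle, config=ClassifierConfig(n_permutations=1000, seed=5)
    )


@pytest.fixture(scope="session")
def small_session():
    """Cheap mixed session for plumbing tests."""
    config = SessionConfig(n_trials=30, seed=3)
    specs = (
        [NeuronSpec("Trigger-like")] * 3
        + [NeuronSpec("Rewarded")] * 3
        + [NeuronSpec("Poking-OFF")] * 2
        + [NeuronSpec("Other", response_amplitude=0.0)] * 4
    )
    bundle, truth = simulate_session(config, specs)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
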