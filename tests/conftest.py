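import pytest

from crforest.classifier import TrainConfig, train_pipeline
from crforest.synthetic_data import make_training_repeats


@pytest.fixture(scope="session")
def trained_model():
    """A compact classifier trained on synthetic stem-loop repeats vs
    Markov negatives; shared across tests that only need *a* model."""
    positives = make_training_repeats(400, rng_seed=11)
    model, metrics, _ = train_pipeline(
        positives, config=TrainConfig(ntree=150, rng_seed=11))
    assert metrics.accuracy > 0.85  # sanity: fixture model must be usable
    return model
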