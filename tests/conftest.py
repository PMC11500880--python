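import numpy as np
import pytest

from igpa import LabelVector, PredictionMatrix, SimulatorConfig, simulate_predictions


def random_prediction(rng, n, k, source_id=""):
    """Row-stochastic matrix from Dirichlet rows."""
    return PredictionMatrix(
        rng.dirichlet(np.ones(k), size=n),
        tuple(f"C{i}" for i in range(k)),
        source_id=source_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simulated_bank():
    """Three classifiers of unequal skill over the default imbalanced classes."""
    cfg = SimulatorConfig(
        n_samples=2000, classifier_accuracies=(0.95, 0.70, 0.70), seed=11
    )
    return simulate_predictions(cfg)


@pytest.fixture
def labels_factory():
    def make(values, n_classes=None):
        return LabelVector(np.asarray(values), n_classes=n_classes)

    return make
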