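import numpy as np
import pytest

from mlpitfalls import LabeledTable


@pytest.fixture
def tiny_table() -> LabeledTable:
    """6 samples x 4 features with fixed printed values for hand-checking.

    feature_0 equals the label exactly; feature_3 is constant.
    """
    features = np.array(
        [
            [0.0, 1.0, 2.0, 7.0],
            [0.0, 2.0, 1.5, 7.0],
            [0.0, 1.5, 2.5, 7.0],
            [1.0, 4.0, 2.1, 7.0],
            [1.0, 5.0, 1.9, 7.0],
            [1.0, 4.5, 2.4, 7.0],
        ]
    )
    labels = np.array([0, 0, 0, 1, 1, 1])
    patients = np.array([f"P{i}" for i in range(6)], dtype=object)
    return LabeledTable(features=features, labels=labels, patient_id=patients)


@pytest.fixture
def imbalanced_table() -> LabeledTable:
    """100 noise rows, 10 positive: the oversampling scenario."""
    rng = np.random.default_rng(42)
    labels = np.zeros(100, dtype=int)
    labels[:10] = 1
    labels = labels[rng.permutation(100)]
    return LabeledTable(
        features=rng.standard_normal((100, 5)),
        labels=labels,
        patient_id=np.array([f"P{i:03d}" for i in range(100)], dtype=object),
    )
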