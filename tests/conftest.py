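import numpy as np
import pytest

from rpcabiome import AbundanceMatrix, LabelVector, SyntheticSpec, generate


@pytest.fixture()
def small_matrix() -> AbundanceMatrix:
    """3 taxa x 4 samples, hand-written values."""
    values = np.array(
        [
            [0.2, 0.1, 0.4, 0.25],
            [0.3, 0.6, 0.1, 0.25],
            [0.5, 0.3, 0.5, 0.5],
        ]
    )
    return AbundanceMatrix(values, ("taxA", "taxB", "taxC"), ("s1", "s2", "s3", "s4"))


@pytest.fixture()
def small_labels() -> LabelVector:
    return LabelVector(("H", "H", "D", "D"), positive_class="D")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: p=300, 40+40 samples, 20 planted markers."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def default_detection(default_dataset):
    from rpcabiome import detect_biomarkers

    return detect_biomarkers(default_dataset.matrix, 20)
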