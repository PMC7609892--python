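import numpy as np
import pytest

from lrfusion import GeneratorConfig, LabeledDataset, generate_biomarker_like


@pytest.fixture
def sep1d() -> LabeledDataset:
    """1-D toy with the classes perfectly separated: neg {1,2,3}, pos {4,5,6}."""
    return LabeledDataset(
        features=np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
        labels=np.array([0, 0, 0, 1, 1, 1]),
        variable_names=("x",),
    )


@pytest.fixture
def overlap1d() -> LabeledDataset:
    """1-D toy with overlapping classes: neg {1,2,3}, pos {2.5, 3.5}."""
    return LabeledDataset(
        features=np.array([[1.0], [2.0], [3.0], [2.5], [3.5]]),
        labels=np.array([0, 0, 0, 1, 1]),
        variable_names=("x",),
    )


@pytest.fixture(scope="session")
def study_panel() -> LabeledDataset:
    """The default synthetic biomarker panel: n=125, k=8, two separating
    markers — the study-scale dataset used across modules."""
    return generate_biomarker_like(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def overlapping_panel() -> LabeledDataset:
    """Same structure but with no enforced separation (gap 0)."""
    return generate_biomarker_like(GeneratorConfig(separation_gap=0.0, seed=11))


def make_logistic_toy(n=80, beta=(0.3, 1.2), seed=3) -> LabeledDataset:
    from lrfusion import generate_logistic

    return generate_logistic(n, np.asarray(beta, dtype=float), seed=seed)
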