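import numpy as np
import pytest

from fungirec import (
    GenerativeModel,
    LabelSpace,
    PosteriorMatrix,
    PriorVector,
    build_model,
)


@pytest.fixture
def abc_space():
    return LabelSpace(("A", "B", "C"))


@pytest.fixture
def row_post(abc_space):
    """Single-row posterior used by the hand-derived examples."""
    return PosteriorMatrix(np.array([[0.6, 0.3, 0.1]]), ("o1",), abc_space)


@pytest.fixture
def small_model():
    """K=5, V=7 generative model used by the oracle-equivalence suites."""
    return build_model(
        k=5,
        v=7,
        metadata_cardinalities={"habitat": 3, "substrate": 4},
        concentrations=0.5,
        train_exponent=1.0,
        test_exponent=0.3,
        seed=11,
    )


@pytest.fixture
def hand_model():
    """K=2, V=2 model with hand-set channels (exact fractions checkable)."""
    space = LabelSpace(("A", "B"))
    uniform = PriorVector(np.array([0.5, 0.5]))
    visual = np.array([[0.9, 0.1], [0.2, 0.8]])
    channels = {
        "habitat": np.array([[0.3, 0.7], [0.7, 0.3]]),
        "substrate": np.array([[0.5, 0.5], [0.5, 0.5]]),
        "month": np.full((2, 12), 1 / 12),
    }
    return GenerativeModel(space, uniform, uniform, visual, channels)
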