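import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from strascope import BackgroundModel, MotifMatrix


@pytest.fixture
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


@pytest.fixture
def purine_bg() -> BackgroundModel:
    """Purine-rich background under which pyrimidine motifs are informative."""
    marginal = np.array([0.475, 0.025, 0.475, 0.025])
    return BackgroundModel(marginal, np.tile(marginal, (4, 1)), order=1)


@pytest.fixture
def uc_motif() -> MotifMatrix:
    """Near-deterministic width-2 motif with consensus UC."""
    probs = np.array(
        [
            [0.01, 0.01],
            [0.01, 0.97],
            [0.01, 0.01],
            [0.97, 0.01],
        ]
    )
    return MotifMatrix("UC2", probs)


def random_motif(rng: np.random.Generator, width: int) -> MotifMatrix:
    """A random PPM, Dirichlet-ish with occasional near-deterministic columns."""
    cols = []
    for _ in range(width):
        alpha = rng.uniform(0.2, 2.0, size=4)
        col = rng.dirichlet(alpha)
        cols.append(col)
    return MotifMatrix(f"rand{rng.integers(1 << 30)}", np.column_stack(cols))


def random_background(rng: np.random.Generator) -> BackgroundModel:
    marginal = rng.dirichlet(np.full(4, 2.0))
    marginal = np.clip(marginal, 0.02, None)
    marginal /= marginal.sum()
    transition = np.tile(marginal, (4, 1))
    return BackgroundModel(marginal, transition, order=1)
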