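import logging

import numpy as np
import pytest

from paceshape.cohort import Cohort, FrondRecord
from paceshape.simulate import paper_like_config, simulate_cohort

# the simulator logs a clipping warning per affected frond; keep test output readable
logging.getLogger("paceshape.simulate").setLevel(logging.ERROR)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Five hand-built fronds over 2 species x 2 blocks, one excluded."""
    return Cohort(
        fronds=[
            FrondRecord("f1", "A", "B1", [0, 1, 1]),
            FrondRecord("f2", "A", "B1", [0, 0, 1, 0, 1]),
            FrondRecord("f3", "A", "B2", [1, 1]),
            FrondRecord("f4", "B", "B1", [0, 1]),
            FrondRecord("f5", "B", "B1", [1, 0, 2, 1]),
            FrondRecord(
                "f6", "B", "B2", [0, 0], excluded=True, exclusion_reason="contamination"
            ),
            FrondRecord("f7", "B", "B2", [0, 1, 1, 1]),
        ]
    )


@pytest.fixture(scope="session")
def paper_cohort() -> Cohort:
    """One paper-like simulated cohort (3 species x 4 blocks x 37 fronds)."""
    return simulate_cohort(paper_like_config(seed=11))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
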