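import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from feasipath.coexpression import SampleCovariates
from feasipath.reconstruction import MetabolicReconstruction, Reaction
from feasipath.simulate import make_fig1_reconstruction


@pytest.fixture(scope="session")
def fig1_recon():
    return make_fig1_reconstruction()


@pytest.fixture(scope="session")
def toy_recon():
    """r1: A converts C1->C2; r2/r3: B converts C2->C3 and C3->C4."""
    rows = [
        ("r1", "A", {"C1"}, {"C2"}),
        ("r2", "B", {"C2"}, {"C3"}),
        ("r3", "B", {"C3"}, {"C4"}),
    ]
    return MetabolicReconstruction(
        tuple(Reaction(r, frozenset({g}), frozenset(s), frozenset(p)) for r, g, s, p in rows)
    )


def random_covariates(n: int, rng: np.random.Generator, levels=(2, 2, 2)) -> SampleCovariates:
    """Randomized (non-confounded with probability ~1) two-level factors."""
    def factor(prefix, k):
        v = [f"{prefix}{i % k}" for i in range(n)]
        rng.shuffle(v)
        return v

    return SampleCovariates(
        pd.DataFrame(
            {
                "batch": factor("b", levels[0]),
                "sex": factor("s", levels[1]),
                "nationality": factor("n", levels[2]),
            },
            index=[f"S{i:03d}" for i in range(n)],
        )
    )


@pytest.fixture
def make_covariates():
    return random_covariates
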