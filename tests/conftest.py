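import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `import oracles` work

from grnrestore import CTMParameters, NetworkStructure


@pytest.fixture
def chain3():
    """3-gene chain 0 -> 1 -> 2 with one pair term on gene 2... kept linear."""
    return NetworkStructure(
        p=3,
        linear_sets=[set(), {0}, {1}],
    )


@pytest.fixture
def linear_params_chain3(chain3):
    """Stable linear parameters on the 3-gene chain (no pair terms)."""
    params = CTMParameters.zeros(chain3, q=0.05, r=0.2)
    np.fill_diagonal(params.a, -0.6)  # multiplier 0.4
    params.a[1, 0] = 0.5
    params.a[2, 1] = -0.4
    params.u = np.array([0.3, -0.2, 0.1])
    params.mu0 = np.array([1.0, 0.0, -0.5])
    params.sigma0_diag = np.array([0.5, 0.5, 0.5])
    return params


def make_quadratic_structure():
    """p=3 structure where gene 2 has a pair term on regulators (0, 1)."""
    return NetworkStructure(
        p=3,
        linear_sets=[set(), {0}, {0, 1}],
        pair_sets=[set(), set(), {(0, 1)}],
    )


def make_quadratic_params():
    s = make_quadratic_structure()
    params = CTMParameters.zeros(s, q=0.05, r=0.2)
    np.fill_diagonal(params.a, -0.7)
    params.a[1, 0] = 0.6
    params.a[2, 0] = 0.3
    params.a[2, 1] = -0.5
    params.b = {(2, (0, 1)): 0.4}
    params.u = np.array([0.4, -0.1, 0.2])
    params.mu0 = np.array([0.8, 0.2, -0.3])
    params.sigma0_diag = np.full(3, 0.5)
    return s, params
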