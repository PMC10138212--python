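import numpy as np
import pytest

from codescape.codons import EnsembleConstraints, sgc
from codescape.cost import CostEvaluator
from codescape.synthetic import make_toy


@pytest.fixture(scope="session")
def evaluator():
    return CostEvaluator()


@pytest.fixture(scope="session")
def standard_code():
    return sgc()


@pytest.fixture(scope="session")
def default_constraints():
    return EnsembleConstraints()


@pytest.fixture(scope="session")
def toy36():
    """4 binary-pair codons, 3 symbols, surjective: 36 enumerable states."""
    return make_toy(2, 2, 3, seed=1)


@pytest.fixture(scope="session")
def toy_large():
    """2-base, 3-letter codons (8 sites), 3 symbols: 6561 states."""
    return make_toy(2, 3, 3, seed=7)
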