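import numpy as np
import pytest
from hypothesis import settings

from adema import parse_network

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def chain_network():
    """Linear chain A -> B -> C with A, C external (one mode)."""
    return parse_network(
        "external: A C\n"
        "R1: A -> B\n"
        "R2: B -> C\n"
    )


@pytest.fixture
def branch_network():
    """Branch A -> B, B -> C, B -> D with A, C, D external (two modes)."""
    return parse_network(
        "external: A C D\n"
        "R1: A -> B\n"
        "R2: B -> C\n"
        "R3: B -> D\n"
    )


@pytest.fixture
def measured_chain_network():
    """All-internal chain with boundary exchanges, for subset strategies."""
    return parse_network(
        "external: X Y\n"
        "R0: X -> A\n"
        "R1: A -> B\n"
        "R2: B -> C\n"
        "R3: C -> Y\n"
    )


def random_binned_cohort(rng, n, d, M, k=None):
    """A random soft-binned probability tensor with rows summing to 1, plus
    a random two-class label split with at least one sample per class."""
    from adema.binning import BinnedCohort

    if k is None:
        k = M
    probs = rng.dirichlet(np.ones(M), size=(n, d))
    labels = np.array(["control"] * n, dtype=object)
    n_var = int(rng.integers(1, n))
    labels[rng.choice(n, n_var, replace=False)] = "variable"
    ranges = np.tile([0.0, 1.0], (d, 1))
    return BinnedCohort(probs=probs, ranges=ranges, M=M, k=k), labels


@pytest.fixture
def make_random_binned():
    return random_binned_cohort
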