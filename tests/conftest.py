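import numpy as np
import pytest

from contrastinfo import DiscreteJoint, DTMCModel


def random_joint(rng, shape=(3, 3, 3), zeros=0.0) -> DiscreteJoint:
    """A seeded random joint pmf; `zeros` is the fraction of cells emptied."""
    pmf = rng.random(shape) + 1e-3
    if zeros:
        mask = rng.random(shape) < zeros
        pmf[mask] = 0.0
    pmf /= pmf.sum()
    labels = lambda k, tag: tuple(f"{tag}{i}" for i in range(k))
    return DiscreteJoint(
        labels(shape[0], "a"), labels(shape[1], "b"), labels(shape[2], "c"), pmf
    )


def random_dtmc(rng, n_states=None) -> DTMCModel:
    """A seeded random irreducible chain with strictly positive entries."""
    n = n_states or int(rng.integers(2, 7))
    P = rng.random((n, n)) + 0.05
    P /= P.sum(axis=0)
    return DTMCModel(tuple(f"s{i}" for i in range(n)), P)


@pytest.fixture
def example1_chain() -> DTMCModel:
    """The two-state stop-light chain: stay .95, switch .05."""
    P = np.array([[0.95, 0.05], [0.05, 0.95]])
    return DTMCModel(("RED", "GREEN"), P)
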