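import numpy as np
import pytest

from causalq import MarginSet, StatisticKind


def random_margins(rng: np.random.Generator, n_max: int = 12,
                   mixed: bool = True) -> MarginSet:
    """A random consistent margin set with N <= n_max.

    ``mixed=True`` allows a nonzero unsigned row (4x3 shape); otherwise
    the margins are 3x3 (q_r == 0).
    """
    n = int(rng.integers(1, n_max + 1))
    q_r = int(rng.integers(0, n + 1)) if mixed else 0
    rest = n - q_r
    c = sorted(int(v) for v in rng.integers(0, rest + 1, size=2))
    c2 = sorted(int(v) for v in rng.integers(0, n + 1, size=2))
    return MarginSet(q_plus=c[0], q_minus=c[1] - c[0], q_r=q_r,
                     q_zero=rest - c[1], n_plus=c2[0],
                     n_minus=c2[1] - c2[0], n_zero=n - c2[1])


def kind_for(margins: MarginSet) -> StatisticKind:
    return (StatisticKind.QUATERNARY if margins.q_r
            else StatisticKind.CORRECTNESS)


@pytest.fixture
def rng():
    return np.random.default_rng(20160824)


@pytest.fixture
def toy_network():
    """Regulator X with one +, one - and one unsigned target."""
    from causalq import collapse_conflicts
    return collapse_conflicts([("X", "a", "+"), ("X", "b", "-"),
                               ("X", "c", "r")])


@pytest.fixture
def toy_profile():
    from causalq import DEProfile
    return DEProfile(values={"a": 1, "b": -1, "c": 1, "d": 0})
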