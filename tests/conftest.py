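import numpy as np
import pandas as pd
import pytest

from grntopo.grn_io import RegulatoryInteraction, build_network
from grntopo.synthetic_data import generate_worked_fixture


@pytest.fixture
def two_star():
    """The 10-node / 9-edge two-hub network (focal K_nn = 1.8)."""
    return generate_worked_fixture()


@pytest.fixture
def small_network():
    """[A→B, A→C, D→A]: A=both, D=regulator, B=C=target."""
    return build_network(
        [
            RegulatoryInteraction("A", "B"),
            RegulatoryInteraction("A", "C"),
            RegulatoryInteraction("D", "A"),
        ],
        name="small",
    )


def make_table(n_per_class: int, rule: str, seed: int = 0) -> pd.DataFrame:
    """Small categorical instance tables for learning tests.

    ``rule="separable"``: attribute X fully determines the class.
    ``rule="noise"``: all attributes independent of the class.
    """
    rng = np.random.default_rng(seed)
    classes = ["regulator"] * n_per_class + ["target"] * n_per_class
    n = len(classes)
    bins = np.array(list("ABCDEF"))
    df = pd.DataFrame(
        {
            "X": ["A" if c == "regulator" else "D" for c in classes]
            if rule == "separable"
            else rng.choice(bins, n),
            "Y": rng.choice(bins, n),
            "Z": rng.choice(bins, n),
            "class": classes,
        },
        index=[f"g{i}" for i in range(n)],
    )
    return df


@pytest.fixture
def separable_table():
    return make_table(100, "separable")


@pytest.fixture
def noise_table():
    return make_table(100, "noise", seed=3)
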