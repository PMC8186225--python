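import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ssrpop.marker_stats import BandMatrix

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def hand_band_matrix() -> BandMatrix:
    """4 accessions x 4 fragments with hand-computable statistics.

    f1: f=0.5 (PIC 0.5, Ib 1); f2: f=1 (monomorphic); f3: f=0.25
    (PIC 0.375, Ib 0.5); f4: f=0.5.  Primer P1 owns f1, f2; P2 owns f3, f4.
    """
    values = pd.DataFrame(
        {
            "f1": [1, 1, 0, 0],
            "f2": [1, 1, 1, 1],
            "f3": [1, 0, 0, 0],
            "f4": [0, 1, 1, 0],
        },
        index=["A1", "A2", "A3", "A4"],
    )
    primers = {"f1": "P1", "f2": "P1", "f3": "P2", "f4": "P2"}
    meta = pd.DataFrame(
        {
            "origin": ["Asia", "Asia", "Europe", "Europe"],
            "status": ["Wild", "Cultivar", "Wild", "Cultivar"],
        },
        index=["A1", "A2", "A3", "A4"],
    )
    return BandMatrix(values, primers, meta)


@pytest.fixture(scope="session")
def structured_panel():
    """Moderate 3-group simulated panel shared by slower tests."""
    from ssrpop.synthetic_data import SimPopulationSpec, simulate_band_matrix

    return simulate_band_matrix(
        SimPopulationSpec(n_groups=3, accessions_per_group=8, theta=0.5, seed=202)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
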