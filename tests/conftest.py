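import warnings

import numpy as np
import pytest

from tmdimer.structures import build_ideal_cg_helix
from tmdimer.synthetic import DEFAULT_STATES, MarkovInterfaceModel, place_dimer


@pytest.fixture(scope="session")
def ideal_helix():
    """25-residue ideal CG helix numbered 72-96 (transmembrane segment)."""
    return build_ideal_cg_helix(25, first_residue=72)


@pytest.fixture(scope="session")
def default_model():
    return MarkovInterfaceModel(seed=1234)


@pytest.fixture(scope="session")
def state_frames(ideal_helix):
    """One noiseless frame per default planted interface state."""
    frames = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for state in DEFAULT_STATES:
            frames[state.state_id] = place_dimer(ideal_helix, ideal_helix, state)
    return frames


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
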