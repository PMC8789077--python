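import logging

import numpy as np
import pytest
from hypothesis import settings

from rnacat import NoiseSpec, generate_assay

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from rnacat.presets import STANDARD_TIMES_H, paper_like, standard_conditions

# the clipping warning is expected whenever noisy fixtures are reduced
logging.getLogger("rnacat.quantify").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def times():
    return np.array(STANDARD_TIMES_H)


@pytest.fixture(scope="session")
def conditions():
    return standard_conditions()


@pytest.fixture(scope="session")
def paper_params():
    return paper_like()


@pytest.fixture(scope="session")
def noiseless_assay(paper_params):
    """Noiseless standard-design fixture from the paper-like preset."""
    eq, kin = paper_params
    return generate_assay(eq, kin, noise=NoiseSpec(0.0, seed=1))
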