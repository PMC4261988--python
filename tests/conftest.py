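import math

import numpy as np
import pytest

from ecotypeabc.demographic_models import Deme, DemographicScenario, Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def panmictic():
    """A single panmictic deme of diploid size 1000."""
    return DemographicScenario(
        "panmictic",
        (Deme("pop", 1000.0),),
        (Epoch(0.0, math.inf, np.zeros((1, 1))),),
        (),
    )


def island_arrays(four_nm: float, deme_size: float = 1000.0) -> dict:
    """Compiled-array form of a symmetric two-deme island model with
    scaled migration 4Nm (no merge events: coalescence via migration)."""
    m = four_nm / (4.0 * deme_size)
    return {
        "sizes": np.array([deme_size, deme_size]),
        "epoch_starts": np.zeros(1),
        "migration": np.array([[[0.0, m], [m, 0.0]]]),
        "ev_time": np.zeros(0),
        "ev_kind": np.zeros(0, dtype=np.int64),
        "ev_a": np.zeros(0, dtype=np.int64),
        "ev_b": np.zeros(0, dtype=np.int64),
        "ev_size": np.zeros(0),
    }
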