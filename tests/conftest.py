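import numpy as np
import pandas as pd
import pytest

import lkdfba as lk


@pytest.fixture(scope="session")
def branched_network():
    return lk.branched_pathway_network()


@pytest.fixture(scope="session")
def reference_model():
    return lk.reference_branched_model()


@pytest.fixture(scope="session")
def reference_data(reference_model):
    """Noiseless ground truth on the default 50-point grid."""
    return lk.simulate_ode(reference_model)


@pytest.fixture
def single_reaction_network():
    """x1 -> x2, no regulation."""
    return lk.MetabolicNetwork(["x1", "x2"], ["v1"], np.array([[-1.0], [1.0]]))


@pytest.fixture
def influx_network():
    """Single metabolite fed by one influx reaction."""
    return lk.MetabolicNetwork(["x"], ["v_in"], np.array([[1.0]]))


def make_dataset(times, conc: dict, fluxes: dict | None = None):
    times = np.asarray(times, dtype=float)
    idx = pd.Index(times, name="time")
    return lk.TimecourseDataset(
        times,
        pd.DataFrame(conc, index=idx),
        pd.DataFrame(fluxes, index=idx) if fluxes is not None else None,
    )
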