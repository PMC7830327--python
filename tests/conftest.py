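import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ramanmcr import synth
from ramanmcr.io import HyperspectralDataset, Spectrum

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_dataset(A, groups=None, cells=None, axis=None):
    """Small hand-made dataset helper."""
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    axis = np.arange(m, dtype=float) if axis is None else np.asarray(axis, float)
    groups = ["g0"] * n if groups is None else list(groups)
    cells = [f"c{i}" for i in range(n)] if cells is None else list(cells)
    meta = pd.DataFrame(
        {
            "id": [f"{c}_{i}" for i, c in enumerate(cells)],
            "cell_id": cells,
            "group": groups,
            "point": list(range(n)),
        }
    )
    return HyperspectralDataset(axis, A, meta)


@pytest.fixture(scope="session")
def small_world():
    """Coarse-grid 7-component study: fast enough for unit tests."""
    cfg = synth.GeneratorConfig(seed=0, n_cells_per_group=10, wn_step=4.0)
    return synth.simulate_cells(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """One default-sized simulated study shared by the slower tests."""
    return synth.simulate_cells(synth.GeneratorConfig(seed=0))


@pytest.fixture()
def spectrum_pair():
    wn = np.linspace(500.0, 600.0, 101)
    s1 = Spectrum(wn, np.ones_like(wn), {"cell_id": "a", "group": "g", "point": 0})
    s2 = Spectrum(wn, 2 * np.ones_like(wn), {"cell_id": "a", "group": "g", "point": 1})
    return s1, s2
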