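import numpy as np
import pandas as pd
import pytest

from tractstats import SimulationSpec, demographics_frame, generate
from tractstats.data_model import DEFAULT_PROFILE_SCHEMA, TractProfileDataset


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down simulation: fewer subjects and nodes, for fast tests."""
    return SimulationSpec(n_td=10, n_asd=12, node_grid=30, seed=42,
                          corr_length=4.0)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def study_sim():
    """Study-scale default conditions (22 TD / 28 ASD, 100 nodes)."""
    return generate(SimulationSpec(seed=7))


@pytest.fixture()
def demo_frame(small_sim):
    return demographics_frame(small_sim[1])


@pytest.fixture()
def tiny_long_frame():
    """Well-formed long-format table: 2 subjects x 1 tract x 5 nodes."""
    rng = np.random.default_rng(0)
    rows = []
    for s in ("s1", "s2"):
        for node in range(5):
            ad = 1.2e-3 * (1 + 0.05 * rng.standard_normal())
            rd = 0.5e-3 * (1 + 0.05 * rng.standard_normal())
            rows.append({
                "subjectID": s, "tractID": "L_AF", "nodeID": node,
                "dti_fa": (ad - rd) / np.sqrt(ad**2 + 2 * rd**2),
                "dti_md": (ad + 2 * rd) / 3, "dti_rd": rd, "dti_ad": ad,
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_dataset(tiny_long_frame):
    return TractProfileDataset.from_long(tiny_long_frame,
                                         DEFAULT_PROFILE_SCHEMA)
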