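import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tcrpmhc as t
from tcrpmhc.contacts import ContactTable


@pytest.fixture(scope="session")
def toy_complex():
    """Synthetic complex with the 12-6-like docking geometry."""
    return t.make_toy_tcr_pmhc(
        t.ToyComplexSpec(crossing_angle=51.0, incident_angle=20.0,
                         x_pos=2.5, y_pos=-1.0)
    )


@pytest.fixture(scope="session")
def planted_complex():
    """Synthetic complex realizing the printed 12-6 peptide contact layout
    (3 CDR3a + 61 CDR3b contacts, total 64)."""
    return t.make_toy_tcr_pmhc(
        t.ToyComplexSpec(
            crossing_angle=51.0, incident_angle=20.0,
            contact_layout={"CDR3a": {"peptide": 3}, "CDR3b": {"peptide": 61}},
        )
    )


@pytest.fixture(scope="session")
def table_12_6():
    """ContactTable holding the printed 12-6 per-CDR contact counts."""
    counts = {}
    mhc = dict(zip(("CDR1a", "CDR2a", "HV4a", "CDR3a",
                    "CDR1b", "CDR2b", "HV4b", "CDR3b"),
                   (5, 39, 0, 28, 5, 3, 0, 12)))
    pep = dict(zip(("CDR1a", "CDR2a", "HV4a", "CDR3a",
                    "CDR1b", "CDR2b", "HV4b", "CDR3b"),
                   (0, 0, 0, 3, 0, 0, 0, 61)))
    for loop, n in mhc.items():
        counts[(loop, "mhc")] = n
    for loop, n in pep.items():
        counts[(loop, "peptide")] = n
    return ContactTable(counts=counts)


def random_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.uniform(-50, 50, size=3)
    return rotation, translation


@pytest.fixture
def rigid_transform():
    return random_rigid_transform
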