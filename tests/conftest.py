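import numpy as np
import pytest

from rescaff import fixtures, rescaffold


@pytest.fixture(scope="session")
def helix12():
    return fixtures.ideal_helix(12)


@pytest.fixture(scope="session")
def donor():
    """Two-helix donor: segments at indices 3-14 (k1=11) and 21-24 (k2=3)."""
    return fixtures.two_segment_donor(k1=11, k2=3, gap=6, flank=3, seed=0)


@pytest.fixture(scope="session")
def query(donor):
    # author numbering starts at 1: segment residues 4-15 and 22-25
    return rescaffold.build_query(donor, "A", (4, 15), (22, 25), None)


@pytest.fixture(scope="session")
def planted(donor):
    """Subject chain with a rigidly moved copy of the donor embedded at a
    known offset, flanked by decoy coils."""
    subject, offset = fixtures.planted_motif_subject(donor, seed=42)
    return subject, offset


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
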