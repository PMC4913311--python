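import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hybridfold.aligner import ScoringParams
from hybridfold.fixtures import make_backbone, make_toy_databank


@pytest.fixture(scope="session")
def toy():
    """Small toy databank: 5 folds x 2 members, 40 residues."""
    return make_toy_databank(n_folds=5, members_per_fold=2, length=40, seed=11)


@pytest.fixture(scope="session")
def default_params():
    return ScoringParams()


@pytest.fixture()
def helix_chain():
    """20-residue ideal alpha helix (phi=-57, psi=-47)."""
    return make_backbone([(-57.0, -47.0, 20)])
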