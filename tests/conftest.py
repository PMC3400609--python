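import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tbdtscan import AlignmentParams, default_family_specs, default_models
from tbdtscan.records import AMINO_ACIDS, ProteinSeq


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def family_specs():
    return default_family_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(20120719)


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def make_protein(rng):
    def _make(length, seq_id="q"):
        return ProteinSeq(seq_id, random_protein(rng, length))
    return _make
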