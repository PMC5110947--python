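import numpy as np
import pytest

from gnmhot.gnm import GNMParameters, build_kirchhoff, decompose
from gnmhot.structure_io import CaChain
from gnmhot.synthetic import SyntheticSpec, generate_chain


def make_chain(coords, chain_id="A", start=1):
    coords = np.asarray(coords, dtype=float)
    residues = tuple((start + i, "", "GLY") for i in range(coords.shape[0]))
    return CaChain(chain_id=chain_id, residues=residues, coords=coords)


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def synth_chains(synth_spec):
    """Twenty seeded self-avoiding-walk chains shared across tests."""
    return [generate_chain(synth_spec, i) for i in range(20)]


@pytest.fixture(scope="session")
def spectrum_10(synth_chains):
    """Spectrum of one mid-sized synthetic chain at the standard cutoff."""
    params = GNMParameters(cutoff=7.0)
    return decompose(build_kirchhoff(synth_chains[0], params), params), params
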