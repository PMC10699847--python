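import numpy as np
import pytest

from foldeval import (StructureModel, backbone_frames, extract_torsions,
                      make_peptide)


@pytest.fixture(scope="session")
def mixed_peptide() -> StructureModel:
    """A 10-residue helix covering 0-4 chi residues, seeded."""
    return make_peptide("SRLFKDEYWQ", "helix", seed=3)


@pytest.fixture(scope="session")
def mixed_torsions(mixed_peptide):
    return extract_torsions(mixed_peptide)


@pytest.fixture(scope="session")
def mixed_frames(mixed_peptide):
    return backbone_frames(mixed_peptide)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
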