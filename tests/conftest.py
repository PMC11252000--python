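import pytest
from hypothesis import settings

from peptiport.peptide_chem import DipeptideSpec

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def his_glu() -> DipeptideSpec:
    """His–Glu with side-chain pKa 6.0 / 4.1 (four-state model)."""
    return DipeptideSpec.from_residues("H", "E")


@pytest.fixture
def his_ala() -> DipeptideSpec:
    return DipeptideSpec.from_residues("H", "A")


@pytest.fixture
def lys_ala() -> DipeptideSpec:
    return DipeptideSpec.from_residues("K", "A")
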