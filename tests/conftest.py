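import numpy as np
import pytest

from pyrosite.masschem import ModifiedPeptide, mz, peptide_neutral_mass
from pyrosite.simulate import SimConfig, make_standard_fixtures
from pyrosite.spectra_io import SpectrumRecord


@pytest.fixture(scope="session")
def standards() -> dict[str, ModifiedPeptide]:
    return make_standard_fixtures()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240425)


@pytest.fixture
def sim_cfg() -> SimConfig:
    return SimConfig()


def make_cid(
    peptide: ModifiedPeptide,
    z: int,
    peaks: list[tuple[float, float]],
    scan_id: str = "cid",
) -> SpectrumRecord:
    """A CID spectrum for `peptide` at charge `z` with explicit peaks."""
    return SpectrumRecord(scan_id, mz(peptide_neutral_mass(peptide), z), z, "CID", tuple(peaks))


def make_ethcd(
    peptide: ModifiedPeptide,
    z: int,
    peaks: list[tuple[float, float]],
    scan_id: str = "ethcd",
    triggered_by: str | None = None,
) -> SpectrumRecord:
    return SpectrumRecord(
        scan_id,
        mz(peptide_neutral_mass(peptide), z),
        z,
        "EThcD",
        tuple(peaks),
        triggered_by=triggered_by,
    )
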