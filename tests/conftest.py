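import pytest

from pmfkit.digest import DigestParams
from pmfkit.seqmodel import ProteinRecord, Proteoform


@pytest.fixture
def wide_params():
    """Digestion params with no practical length/mass filtering."""
    return DigestParams(min_len=1, mass_window=(1.0, 1e7))


@pytest.fixture
def toy_record():
    return ProteinRecord(id="toy", sequence="AKRGMCWKPLLKAAAK")


@pytest.fixture
def toy_form(toy_record):
    return Proteoform(toy_record)


def make_record(seq: str, rid: str = "p") -> ProteinRecord:
    return ProteinRecord(id=rid, sequence=seq)
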