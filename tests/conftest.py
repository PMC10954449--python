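import pytest

from hybrikin import annotate_duplex, parse_sequence
from hybrikin.synthetic_data import PROBE_SEQ, TARGET_SEQ, paper_preset


@pytest.fixture(scope="session")
def probe():
    return parse_sequence(PROBE_SEQ, "DNA", name="P")


@pytest.fixture(scope="session")
def target():
    return parse_sequence(TARGET_SEQ, "DNA", name="12t")


@pytest.fixture(scope="session")
def perfect_duplex(probe, target):
    return annotate_duplex(target, probe)


@pytest.fixture(scope="session")
def preset():
    return paper_preset()
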