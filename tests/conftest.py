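import pytest
from hypothesis import HealthCheck, settings

from alimask import Alignment

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_nuc():
    return Alignment(
        ids=("a", "b"), rows=("ACGT", "ACGA"), alphabet_kind="nucleotide"
    )


@pytest.fixture
def tiny_aa():
    return Alignment(
        ids=("a", "b", "c"),
        rows=("ARND-X", "ARNDCQ", "ARNERQ"),
        alphabet_kind="amino_acid",
    )
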