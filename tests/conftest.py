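import pytest

from torsionmelt import reference_sequences, reference_parameters


@pytest.fixture(scope="session")
def at_seq():
    return reference_sequences()["AT"]


@pytest.fixture(scope="session")
def gc_seq():
    return reference_sequences()["GC"]


@pytest.fixture(scope="session")
def at_params():
    return reference_parameters("AT")


@pytest.fixture(scope="session")
def gc_params():
    return reference_parameters("GC")
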