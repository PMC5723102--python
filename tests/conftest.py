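import pytest

from moclokit import load_codon_usage, load_enzymes, load_fusion_sites, load_registry


@pytest.fixture(scope="session")
def enzymes():
    return load_enzymes()


@pytest.fixture(scope="session")
def enzyme_list(enzymes):
    return [enzymes["BsaI"], enzymes["BpiI"]]


@pytest.fixture(scope="session")
def fs():
    return load_fusion_sites()


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def usage():
    return load_codon_usage()
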