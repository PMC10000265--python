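import pytest

from phenokit import MetaData, Phenopacket, build_retinoblastoma_example


@pytest.fixture(scope="session")
def retinoblastoma():
    return build_retinoblastoma_example()


@pytest.fixture()
def minimal_phenopacket():
    """Just the two required fields: id and metaData."""
    return Phenopacket(id="minimal", meta_data=MetaData(created="2022-01-01T00:00:00Z"))
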