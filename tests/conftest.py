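import pytest

from radstab import GridSpec, buried_volume
from radstab.fixtures import fixture_library, ideal_methyl


@pytest.fixture(scope="session")
def methyl():
    return ideal_methyl()


@pytest.fixture(scope="session")
def methyl_vbur(methyl):
    struct, _ = methyl
    return buried_volume(struct, 0, GridSpec()).percent_buried


@pytest.fixture(scope="session")
def library():
    return fixture_library()
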