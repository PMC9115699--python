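import pytest

from conduitmap.fixtures import HairpinSpec, make_hairpin, make_protease_mimic, make_sheet


@pytest.fixture(scope="session")
def mimic():
    """Synthetic protease-fold mimic with its ground truth."""
    return make_protease_mimic()


@pytest.fixture(scope="session")
def hairpin_spec():
    return HairpinSpec(strand_length=6, turn_length=2)


@pytest.fixture(scope="session")
def hairpin(hairpin_spec):
    return make_hairpin(hairpin_spec)


@pytest.fixture(scope="session")
def sheet3():
    """Three-strand sheet: anti then para pairing, with ground truth."""
    return make_sheet([6, 6, 6], ["anti", "para"])
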