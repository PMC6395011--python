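import pytest

from rcc5align import check_consistency, infer_mir
from rcc5align.fixtures import (
    fixture_neoaves_zoom,
    fixture_psittaciformes,
)


@pytest.fixture(scope="session")
def psitta_strict():
    return fixture_psittaciformes("strict")


@pytest.fixture(scope="session")
def psitta_relaxed():
    return fixture_psittaciformes("relaxed")


@pytest.fixture(scope="session")
def psitta_strict_mir(psitta_strict):
    return infer_mir(psitta_strict)


@pytest.fixture(scope="session")
def psitta_relaxed_mir(psitta_relaxed):
    return infer_mir(psitta_relaxed)


@pytest.fixture(scope="session")
def zoom():
    return fixture_neoaves_zoom()


@pytest.fixture(scope="session")
def zoom_mir(zoom):
    return infer_mir(zoom)


@pytest.fixture(scope="session")
def zoom_witness(zoom):
    return check_consistency(zoom).witness
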