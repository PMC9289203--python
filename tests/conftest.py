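import pytest

import cecmr


@pytest.fixture(scope="session")
def tables():
    """Bundled trait -> (descriptor, associations) mapping."""
    return cecmr.load_cec_gwas()


@pytest.fixture(scope="session")
def cad_instruments():
    """Five-SNP instrument harmonized against coronary artery disease."""
    return cecmr.instrument_for("CAD")


@pytest.fixture(scope="session")
def mi_instruments():
    return cecmr.instrument_for("MI")


@pytest.fixture(scope="session")
def is_instruments():
    return cecmr.instrument_for("IS")


@pytest.fixture(scope="session")
def single_snp_cad():
    """rs141622900 harmonized against coronary artery disease."""
    (inst,) = cecmr.instrument_for("CAD", cecmr.SINGLE_SNP)
    return inst
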