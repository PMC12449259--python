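import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from scaffhop import build_library, parse_smiles
from scaffhop.cli import generate_fixture_library


@pytest.fixture(scope="session")
def records():
    """Parsed records for molecules used across the suite."""
    names = {
        "benzene": "c1ccccc1",
        "toluene": "Cc1ccccc1",
        "naphthalene": "c1ccc2ccccc2c1",
        "biphenyl": "c1ccc(-c2ccccc2)cc1",
        "phenylpyridine": "c1ccc(-c2ccccn2)cc1",
        "diphenylmethane": "c1ccc(Cc2ccccc2)cc1",
        "indanone": "O=C1CCc2ccccc21",
        "hexane": "CCCCCC",
        "ethanol": "CCO",
        "dimethylbiphenyl": "Cc1ccc(-c2ccc(C)cc2)cc1",
    }
    return {k: parse_smiles(v) for k, v in names.items()}


@pytest.fixture(scope="session")
def toy_library():
    """A small hand-checkable scaffold library."""
    mols = [
        parse_smiles(s)
        for s in (
            "c1ccc(-c2ccccc2)cc1",       # biphenyl
            "c1ccc(-c2ccccn2)cc1",       # 2-phenylpyridine
            "c1ccc2ccccc2c1",            # naphthalene
            "c1cncnc1",                  # pyrimidine
            "c1ccsc1",                   # thiophene
            "C1CCNCC1",                  # piperidine
            "c1ccc(Cc2ccncc2)cc1",       # benzyl-pyridine
        )
    ]
    return build_library(mols, source_tag="toy")


@pytest.fixture(scope="session")
def fixture_library():
    """The bundled fixture library at a size small enough for fast runs."""
    return generate_fixture_library(30, seed=7)
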