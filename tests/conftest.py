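import pytest

from degronscreen.codons import DegenerateCodonScheme, standard_code
from degronscreen.simulate import StabilityRule, sample_library


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def nnn():
    return DegenerateCodonScheme.from_name("NNN")


@pytest.fixture(scope="session")
def nnk():
    return DegenerateCodonScheme.from_name("NNK")


@pytest.fixture()
def small_library():
    """2000-variant NNN library with the default Ile/Leu-at-P1 rule."""
    return sample_library(
        2000, rule=StabilityRule.ile_leu_p1(), seed=42
    )
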