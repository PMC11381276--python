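import pytest

from preclinpk.datamodel import deg_azm_card
from preclinpk.pbpk.physiology import load_physiology


@pytest.fixture(scope="session")
def rat_physiology():
    return load_physiology("rat")


@pytest.fixture(scope="session")
def human_physiology():
    return load_physiology("human")


@pytest.fixture(scope="session")
def compound():
    return deg_azm_card()


@pytest.fixture(scope="session")
def rat_validation_report():
    """Rat PBPK fold-ratio validation under the recorded configuration.

    Session-scoped: the simulation set is reused by the mass-balance and
    acceptance checks.
    """
    from preclinpk.pbpk.validate import validate_rat

    return validate_rat()
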