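import pytest

from onelcode import ABETA42, builtin_code, transcribe


@pytest.fixture(scope="session")
def code():
    return builtin_code()


@pytest.fixture(scope="session")
def abeta_forward(code):
    return transcribe(ABETA42, code, direction="forward", peptide_id="abeta42")


@pytest.fixture(scope="session")
def hur_forward(code):
    # RRM1 N-terminal fragment of the HUR RNA-binding protein
    return transcribe("NLIVNYLPQNMTQDE", code, direction="forward", peptide_id="hur_rrm1")
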