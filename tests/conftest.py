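import pytest

from amplistr.locus import default_ctg18_locus


@pytest.fixture(scope="session")
def locus():
    """The built-in CTG18.1 locus (synthetic flanks, 4,332 bp total)."""
    return default_ctg18_locus()
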