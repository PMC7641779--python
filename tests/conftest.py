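import pytest

from pgxkit.melanoma import build_melanoma_store
from pgxkit.schema import build_default_registry


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def melanoma_store():
    return build_melanoma_store()
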