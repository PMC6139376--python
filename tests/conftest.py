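import pytest

from p2i import load_default_params


@pytest.fixture(scope="session")
def ps():
    """Default parameter registry (session-scoped; frozen dataclasses)."""
    return load_default_params()
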