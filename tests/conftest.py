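import pytest

from piprob import load_builtin_spec


@pytest.fixture(scope="session")
def table2_spec():
    return load_builtin_spec("table2")


@pytest.fixture(scope="session")
def example36_spec():
    return load_builtin_spec("example36")
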