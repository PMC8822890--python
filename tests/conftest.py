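import pytest

from hiitsim import load_builtin


@pytest.fixture(scope="session")
def time_trialist():
    return load_builtin("time_trialist")


@pytest.fixture(scope="session")
def all_rounder():
    return load_builtin("all_rounder")


@pytest.fixture(scope="session")
def sprinter():
    return load_builtin("sprinter")


@pytest.fixture(scope="session")
def profiles(time_trialist, all_rounder, sprinter):
    return (time_trialist, all_rounder, sprinter)
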