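import pytest
from hypothesis import settings

from tautkin import table1_reaction_set, table2_structures

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return table1_reaction_set()


@pytest.fixture(scope="session")
def table2():
    return table2_structures()
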