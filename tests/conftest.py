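import pytest

from reexpress import load_fixture, membership_table


@pytest.fixture(scope="session")
def table1():
    """The packaged 15-study evaluation table."""
    return load_fixture()


@pytest.fixture(scope="session")
def table1_membership(table1):
    return membership_table(table1)
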