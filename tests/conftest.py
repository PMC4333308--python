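import pytest

from rafkit import worked_example


@pytest.fixture(scope="session")
def example5():
    return worked_example(5)


@pytest.fixture(scope="session")
def example3():
    return worked_example(3)


@pytest.fixture(scope="session")
def example5_boundary():
    return worked_example(5, B=4, with_boundary=True)


def family_ids(L):
    """Reaction ids of the aggregation family members in the worked example."""
    return [f"r5_{n}" for n in range(2, L + 1)]


@pytest.fixture(scope="session")
def core():
    return frozenset({"r1", "r2", "r3"})


@pytest.fixture(scope="session")
def periphery5():
    return frozenset({"r4", *family_ids(5)})
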