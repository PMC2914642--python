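import numpy as np
import pytest

from sdpclust import (
    Alignment,
    FamilySpec,
    GroupAssignment,
    build_moment_table,
    generate_family,
)


@pytest.fixture(scope="session")
def small_table():
    """Moment table covering everything the small fixtures need."""
    return build_moment_table(k_max=10, c_max=60)


@pytest.fixture(scope="session")
def concordant_family():
    return generate_family(FamilySpec(pattern="concordant", seed=7))


@pytest.fixture(scope="session")
def random_family():
    return generate_family(FamilySpec(pattern="random", seed=7))


@pytest.fixture
def toy_alignment():
    """Two groups of five with one perfectly discriminating column."""
    rows = [
        "ACDEFGHIKA",
        "ACDEFGHIKA",
        "ACDEFGHIKA",
        "ACDEFGHIKA",
        "ACDEFGHIKA",
        "ACDEFGHIKC",
        "ACDEFGHIKC",
        "ACDEFGHIKC",
        "ACDEFGHIKC",
        "ACDEFGHIKC",
    ]
    ids = tuple(f"s{i}" for i in range(10))
    return Alignment(ids=ids, rows=tuple(rows))


@pytest.fixture
def toy_grouping(toy_alignment):
    labels = tuple("g1" if i < 5 else "g2" for i in range(10))
    return GroupAssignment(ids=toy_alignment.ids, labels=labels)
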