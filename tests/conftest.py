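import pytest

from mitoarch.core import load_builtin_record
from mitoarch.simulate import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def renzhiensis():
    """Coordinate-only record of the T. renzhiensis annotation table."""
    return load_builtin_record("HM744694")


@pytest.fixture(scope="session")
def yunnanensis():
    """Coordinate-only record of the T. yunnanensis annotation table."""
    return load_builtin_record("HM744695")


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default synthetic mitogenome with its ground-truth features."""
    return generate_genome(SyntheticGenomeSpec(seed=11))
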