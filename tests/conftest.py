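import pytest
from hypothesis import HealthCheck, settings

from mdbench.architectures import DomainAnnotation, ProteinRecord
from mdbench.fixtures import FixtureSpec, generate_benchmark

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_protein(seq_id, domains, kingdom=None, length=None, linker=5):
    """Protein with the given domain labels laid out left to right.

    ``domains`` is a list of labels or (label, length) pairs.
    """
    annotations = []
    pos = 1 + linker
    for item in domains:
        label, dom_len = item if isinstance(item, tuple) else (item, 50)
        annotations.append(DomainAnnotation(seq_id, label, pos, pos + dom_len - 1))
        pos += dom_len + linker
    total = length if length is not None else pos
    return ProteinRecord(
        id=seq_id, residues="A" * total, annotations=annotations, kingdom=kingdom
    )


@pytest.fixture
def fig1_query_da00101():
    """HAMP + MCPsignal, the two-domain architecture of the worked example."""
    return make_protein("Q3GCI4", [("HAMP", 51), ("MCPsignal", 71)])


@pytest.fixture
def fig1_target_da01025():
    """CHASE3 + HAMP + MCPsignal: contains da00101 but not vice versa."""
    return make_protein("Q4KE98", [("CHASE3", 60), ("HAMP", 51), ("MCPsignal", 71)])


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic benchmark shared across read-only tests."""
    spec = FixtureSpec(n_architectures=10, seed=11)
    return spec, generate_benchmark(spec)
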