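import pytest

from taclass.operon_model import GeneModel, OperonModel, Promoter
from taclass.synthetic_data import SimConfig, reference_fixture, simulate
from taclass.tir_consensus import consensus_by_variant


def regroup_consensus(tir_calls):
    """{operon_id: {variant: ConsensusCall}} from a flat call list."""
    out = {}
    for (operon_id, variant), cons in consensus_by_variant(tir_calls).items():
        out.setdefault(operon_id, {})[variant] = cons
    return out


@pytest.fixture(scope="session")
def fixture_data():
    return reference_fixture()


@pytest.fixture(scope="session")
def fixture_consensus(fixture_data):
    return regroup_consensus(fixture_data.tir_calls)


@pytest.fixture(scope="session")
def sim_small():
    """A small seeded simulation shared across tests (8 operons, 13 datasets)."""
    return simulate(SimConfig(n_operons_per_class=2, seed=42))


@pytest.fixture
def toy_operon():
    """Antitoxin-first operon with an overlapping downstream RBS (class-1-like)."""
    return OperonModel(
        "toy",
        [
            GeneModel("toy_antitoxin", "antitoxin", 100, 340),
            GeneModel("toy_toxin", "toxin", 337, 622),
        ],
        [Promoter("toy_p1", 10)],
    )
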