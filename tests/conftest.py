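import networkx as nx
import pytest

from omicnet import modules, synth

# Exon lengths of the BRCA2 exons 2-9 region (nt): 106, 249, 109, 50, 41,
# 115, 50, 112; CDS opens 27 nt into exon 2. Seed 3 was chosen so the
# exon-5+7 skip translates without a junction-created stop, as the real
# transcript does.
BRCA2_LIKE_LENGTHS = (106, 249, 109, 50, 41, 115, 50, 112)
BRCA2_LIKE_IDS = ("2", "3", "4", "5", "6", "7", "8", "9")
BRCA2_LIKE_CDS = (27, 822)
BRCA2_LIKE_SEED = 3

PLANTED_SPEC = dict(
    n_nodes=60,
    module_sizes=(20, 20, 20),
    overlap_fraction=0.1,
    p_in=0.9,
    p_out=0.02,
    seed=0,
)


@pytest.fixture(scope="session")
def brca2_like_gm():
    return synth.generate_gene_model(
        BRCA2_LIKE_LENGTHS,
        cds_span=BRCA2_LIKE_CDS,
        seed=BRCA2_LIKE_SEED,
        exon_ids=BRCA2_LIKE_IDS,
        symbol="BRCA2LIKE",
    )


@pytest.fixture(scope="session")
def planted_interactome():
    spec = synth.PlantedNetworkSpec(**PLANTED_SPEC)
    return synth.generate_interactome(spec)


@pytest.fixture(scope="session")
def barbell():
    g = nx.barbell_graph(5, 0)
    return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})


def moduleset_from_members(member_sets: dict[str, set[str]]) -> modules.ModuleSet:
    """Hand-built ModuleSet with unit membership rows (tests only)."""
    import pandas as pd

    nodes = sorted(set().union(*member_sets.values()))
    memb = pd.DataFrame(0.0, index=nodes, columns=sorted(member_sets))
    for label, members in member_sets.items():
        for n in members:
            memb.loc[n, label] = 1.0
    return modules.ModuleSet(
        membership=memb,
        heights=pd.Series(0.0, index=nodes),
        graph=nx.Graph(),
    )
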