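import networkx as nx
import numpy as np
import pytest

from combotox.datatypes import ComboObservation, DrugRecord, AnalysisDataset, Severity, ToxicityLabel
from combotox.network_metrics import InteractionNetwork
from combotox.similarity_metrics import PathwayHierarchy
from combotox.synthetic_data import SimConfig, simulate_observations, simulate_universe


@pytest.fixture
def path_network():
    """a - b - c path graph; identity id_map."""
    g = nx.path_graph(["a", "b", "c"])
    return InteractionNetwork(graph=g, id_map={n: n for n in g})


@pytest.fixture
def toy_hierarchy():
    """Leaf p3 with ancestors p2, p1; protein X in that leaf, Y in leaf q1."""
    return PathwayHierarchy(
        lowest={"X": frozenset({"p3"}), "Y": frozenset({"q1"})},
        all={"X": frozenset({"p1", "p2", "p3"}), "Y": frozenset({"q0", "q1"})},
    )


def make_dataset(drug_targets, smiles=None, pairs=None, score=0.0):
    """Small hand-built dataset: one observation per given pair, bliss only."""
    smiles = smiles or {}
    drugs = {
        d: DrugRecord(drug_id=d, name=d, smiles=smiles.get(d), targets=frozenset(t))
        for d, t in drug_targets.items()
    }
    pairs = pairs or []
    observations = [
        ComboObservation(
            drug_a=a,
            drug_b=b,
            cell_line="cl0",
            synergy={"bliss": score},
            toxicity={"synthetic": ToxicityLabel(level=Severity.MINOR, source="synthetic")},
        )
        for a, b in pairs
    ]
    return AnalysisDataset(drugs=drugs, observations=observations)


@pytest.fixture
def small_universe():
    cfg = SimConfig(n_drugs=30, n_proteins=60, n_pairs=120, seed=42)
    return cfg, simulate_universe(cfg)


@pytest.fixture
def small_bundle(small_universe):
    cfg, universe = small_universe
    return cfg, universe, simulate_observations(cfg, universe)
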