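"""Synthetic drug-combination universe with plantable toxicity trends.

Generates every input the analysis consumes — drugs with SMILES and protein
target sets, a protein interaction network, a pathway hierarchy with
lowest/all-level views, per-pair ordinal toxicity labels, and per-(pair, cell
line) synergy scores — with configurable monotone couplings between toxicity
and either the synergy scores or a chosen pair metric. All output is fully
deterministic under the config seed, at the byte level for emitted files.

Couplings
---------
*Synergy <- toxicity*: each synergy score is drawn as ``z * trend + eps`` where
``z`` is the standardized ordinal toxicity level of the pair and
``eps ~ Normal(0, noise_sd)``; ``trend`` in [-1, 1] plants a known monotone
location shift across severity classes.

*Toxicity <- metric*: a Gaussian copula on ranks reassigns severity labels so
that they correlate (Spearman-wise) with a chosen pair metric at the requested
strength, while preserving the configured marginal class probabilities in
expectation. Rank coupling makes the planted strength invariant to the
metric's marginal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SEVERITY_LABELS, SYNERGY_SCORES, Severity, canonical_pair, normalize_name
from .network_metrics import InteractionNetwork, avg_target_distance, neighbor_jaccard
from .similarity_metrics import Fingerprint, PathwayHierarchy, jaccard, morgan_fingerprint

# ~50 valid drug-like molecules; diversity of scaffolds keeps fingerprint
# Tanimoto values spread over (0, 1) rather than clustered.
SMILES_PALETTE: tuple[str, ...] = (
    "CC(=O)OC1=CC=CC=C1C(=O)O", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",
    "CC(=O)NC1=CC=C(O)C=C1", "CN1CCC[C@H]1C1=CN=CC=C1", "C1=CC=C2C(=C1)C=CC=C2O",
    "OC(=O)C1=CC=CC=C1O", "NC1=CC=C(C=C1)S(N)(=O)=O", "CC1=CC=C(C=C1)S(=O)(=O)NC(=O)NN1CCCCCC1",
    "ClC1=CC2=C(C=C1)N=C(N2)NC1CCCC1", "COC1=CC2=C(C=C1OC)C(=O)C(CC1CCN(CC1)CC1=CC=CC=C1)C2",
    "OCC1=CC=C(O)C=C1", "NCCC1=CC=C(O)C(O)=C1", "CNC[C@H](O)C1=CC=C(O)C(O)=C1",
    "CC(N)CC1=CC=CC=C1", "COC1=CC=C(CCN)C=C1", "OC1=CC=C(CCN)C=C1",
    "ClC1=CC=C(C=C1)C(C1=CC=CC=C1)N1CCN(CCOCCO)CC1", "CCN(CC)CCNC(=O)C1=CC=C(N)C=C1",
    "CC(C)NCC(O)COC1=CC=C(CC(N)=O)C=C1", "CCOC(=O)C1=CC=C(N)C=C1",
    "CN(C)CCCN1C2=CC=CC=C2SC2=CC=CC=C12", "CN(C)CCCN1C2=CC=CC=C2CCC2=CC=CC=C12",
    "OC(=O)CC1=CC=CC=C1N", "CC1=CC(C)=C(C=C1)NC(=O)CN(CC(O)=O)CC(O)=O",
    "NC(=O)C1=CN=CC=C1", "OC(=O)C1=CN=CC=C1", "C1CCNCC1",
    "OCCN1CCN(CCCN2C3=CC=CC=C3SC3=CC=C(Cl)C=C32)CC1",
    "CC(C)(C)NCC(O)C1=CC(O)=CC(O)=C1", "CC(C)(C)NCC(O)COC1=CC=CC2=C1CC(O)C2",
    "COC1=CC=C(C=C1)CC(C)NC", "OC1=CC=C2C=CC=CC2=C1", "NC1=NC2=C(N1)C(=O)N=C(N)N2",
    "CC1=CN(C2CC(O)C(CO)O2)C(=O)NC1=O", "NC1=NC(=O)N(C=C1)C1CC(O)C(CO)O1",
    "OCC1OC(C(O)C1O)N1C=NC2=C1N=CN=C2N", "CC(=O)CC(C1=CC=CC=C1)C1=C(O)C2=CC=CC=C2OC1=O",
    "CCC(C)C1(CC)C(=O)NC(=O)NC1=O", "CC1(C)SC2C(NC(=O)CC3=CC=CC=C3)C(=O)N2C1C(O)=O",
    "CC1=CC2=C(C=C1C)N(CC(O)=O)C(=O)C2", "ClC1=CC=CC(Cl)=C1", "OC1=CC=CC=C1C(=O)NC1=CC=CC=C1",
    "CN1CCN(CC1)C1=NC2=CC=CC=C2NC1=O", "COC(=O)C1=CC=CC=C1O",
    "CCCCC1=NC2(CCCC2)C(=O)N1CC1=CC=C(C=C1)C1=CC=CC=C1C1=NN=NN1",
    "CC(C)C1=NC(=NC(=C1C=CC(O)CC(O)CC(O)=O)C1=CC=C(F)C=C1)N(C)S(C)(=O)=O",
    "OC(=O)C1CN(C)C2CC3=CNC4=CC=CC(=C34)C2=C1", "CC(CS)C(=O)N1CCCC1C(O)=O",
    "NC(CC1=CN=CN1)C(O)=O",
)

SPECIES = "Homo sapiens"


@dataclass
class SimConfig:
    """Generator configuration; identical config + seed give byte-identical files."""

    n_drugs: int = 150
    n_proteins: int = 300
    n_pairs: int = 2000
    targets_per_drug: tuple[int, int] = (1, 5)
    ppin_model: str = "preferential_attachment"  # or "random_geometric"
    ppin_params: dict = field(default_factory=lambda: {"m": 3})
    pathway_depth: int = 4
    pathway_branching: int = 3
    # severity class probabilities (Minor, Moderate, Major); the default is a
    # Major-heavy mix resembling curated DDI severity tables
    toxicity_marginals: tuple[float, float, float] = (0.10, 0.31, 0.59)
    synergy_toxicity_trend: float = 0.0
    metric_toxicity_trend: float = 0.0
    coupling_metric: str = "tanimoto"
    noise_sd: float = 1.0
    db_disagreement: float = 0.0
    cell_lines_range: tuple[int, int] = (1, 3)
    fingerprint_only: bool = False
    fp_bits: int = 2048
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.toxicity_marginals) - 1.0) > 1e-9:
            raise ValueError("toxicity_marginals must sum to 1")
        if self.targets_per_drug[1] > self.n_proteins:
            raise ValueError("targets_per_drug exceeds n_proteins")
        if self.n_pairs > self.n_drugs * (self.n_drugs - 1) // 2:
            raise ValueError("n_pairs exceeds the number of distinct drug pairs")
        if min(self.n_drugs, self.n_proteins, self.n_pairs) <= 0:
            raise ValueError("counts must be positive")
        if not -1.0 <= self.synergy_toxicity_trend <= 1.0:
            raise ValueError("synergy_toxicity_trend must lie in [-1, 1]")
        if not -1.0 <= self.metric_toxicity_trend <= 1.0:
            raise ValueError("metric_toxicity_trend must lie in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class Universe:
    """In-memory synthetic universe; ``display_names`` maps drug_id -> file-facing name."""

    drug_ids: list[str]
    display_names: dict[str, str]
    smiles: dict[str, str]
    targets: dict[str, frozenset[str]]
    proteins: list[str]
    hierarchy: PathwayHierarchy
    network: InteractionNetwork
    fingerprints: Optional[dict[str, Fingerprint]] = None


@dataclass
class ObservationBundle:
    """Synergy rows plus per-pair severity labels in both database dialects."""

    synergy: pd.DataFrame  # synthetic-dialect columns
    toxicity_drugbank: pd.DataFrame  # drug1, drug2, level
    toxicity_ddinter: pd.DataFrame  # drug1, drug2, severity
    labels: dict[tuple[str, str], Severity]  # drugbank-side labels, canonical ids
    labels_ddinter: dict[tuple[str, str], Severity]


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_universe(cfg: SimConfig) -> Universe:
    """Generate drugs, targets, pathway hierarchy, and the interaction network."""
    cfg.validate()
    rng_t, rng_p, rng_s, rng_f = _rngs(cfg.seed, 4)

    display = {f"drug{i:04d}": f"Drug-{i:04d}" for i in range(cfg.n_drugs)}
    drug_ids = sorted(display)
    proteins = [f"P{90000 + i:05d}" for i in range(cfg.n_proteins)]

    lo, hi = cfg.targets_per_drug
    targets = {}
    for d in drug_ids:
        k = int(rng_t.integers(lo, hi + 1))
        idx = sorted(rng_t.choice(cfg.n_proteins, size=k, replace=False).tolist())
        targets[d] = frozenset(proteins[i] for i in idx)

    # pathway tree: complete b-ary tree with `depth` levels; leaves at the
    # bottom; each protein joins exactly one leaf
    depth, b = cfg.pathway_depth, cfg.pathway_branching
    parents: dict[str, Optional[str]] = {}
    levels: list[list[str]] = [["PW-R"]]
    parents["PW-R"] = None
    for lvl in range(1, depth):
        layer = []
        for parent in levels[lvl - 1]:
            for j in range(b):
                node = f"{parent}.{j}"
                parents[node] = parent
                layer.append(node)
        levels.append(layer)
    leaves = levels[-1]
    lowest, all_view = {}, {}
    for p in proteins:
        leaf = leaves[int(rng_p.integers(len(leaves)))]
        chain, cur = [], leaf
        while cur is not None:
            chain.append(cur)
            cur = parents[cur]
        lowest[p] = frozenset([leaf])
        all_view[p] = frozenset(chain)
    hierarchy = PathwayHierarchy(lowest=lowest, all=all_view)

    # PPIN over STRING-style node ids
    nx_seed = int(rng_s.integers(0, 2**31 - 1))
    if cfg.ppin_model == "preferential_attachment":
        g0 = nx.barabasi_albert_graph(cfg.n_proteins, cfg.ppin_params.get("m", 3), seed=nx_seed)
    elif cfg.ppin_model == "random_geometric":
        g0 = nx.random_geometric_graph(cfg.n_proteins, cfg.ppin_params.get("radius", 0.15), seed=nx_seed)
    else:
        raise ValueError(f"unknown ppin_model: {cfg.ppin_model!r}")
    node_of = {i: f"9606.SYN{i:05d}" for i in g0.nodes}
    g = nx.Graph()
    g.add_nodes_from(node_of[i] for i in sorted(g0.nodes))
    g.add_edges_from((node_of[u], node_of[v]) for u, v in sorted(map(sorted, g0.edges)))
    id_map = {proteins[i]: node_of[i] for i in range(cfg.n_proteins)}
    network = InteractionNetwork(graph=g, id_map=id_map)

    smiles = {d: SMILES_PALETTE[int(rng_f.integers(len(SMILES_PALETTE)))] for d in drug_ids}
    fingerprints = None
    if cfg.fingerprint_only:
        fingerprints = {}
        for d in drug_ids:
            bits = (rng_f.random(cfg.fp_bits) < 0.05).astype(np.uint8)
            fingerprints[d] = Fingerprint(bits=bits, n_bits=cfg.fp_bits, radius=0)
        smiles = {}

    return Universe(
        drug_ids=drug_ids,
        display_names=display,
        smiles=smiles,
        targets=targets,
        proteins=proteins,
        hierarchy=hierarchy,
        network=network,
        fingerprints=fingerprints,
    )


def _pair_metric_value(universe: Universe, cfg: SimConfig, a: str, b: str) -> Optional[float]:
    m = cfg.coupling_metric
    ta, tb = universe.targets[a], universe.targets[b]
    if m == "target_jaccard":
        return jaccard(ta, tb) if ta and tb else None
    if m == "tanimoto":
        from .similarity_metrics import tanimoto

        if universe.fingerprints is not None:
            return tanimoto(universe.fingerprints[a], universe.fingerprints[b])
        fa = morgan_fingerprint(universe.smiles[a])
        fb = morgan_fingerprint(universe.smiles[b])
        return tanimoto(fa, fb) if fa is not None and fb is not None else None
    if m == "avg_target_distance":
        return avg_target_distance(ta, tb, universe.network)
    if m == "neighbor_jaccard":
        return neighbor_jaccard(ta, tb, universe.network, k=2)
    raise ValueError(f"unsupported coupling metric: {m!r}")


def _copula_labels(
    metric: np.ndarray, rho: float, marginals: tuple[float, float, float], rng: np.random.Generator
) -> np.ndarray:
    """Severity labels rank-coupled to `metric` at strength rho, marginals preserved."""
    n = len(metric)
    # normal scores of the metric ranks (average ranks for ties)
    u = (stats.rankdata(metric) - 0.5) / n
    a = stats.norm.ppf(u)
    latent = rho * a + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    cuts = stats.norm.ppf(np.cumsum(marginals)[:2])
    return np.digitize(latent, cuts)  # 0/1/2


def simulate_observations(cfg: SimConfig, universe: Universe) -> ObservationBundle:
    """Draw pairs, severity labels, and synergy scores with the planted couplings."""
    cfg.validate()
    _, _, _, _, rng_pairs, rng_tox, rng_syn, rng_dd = _rngs(cfg.seed, 8)

    n_drugs = len(universe.drug_ids)
    all_pairs = [(i, j) for i in range(n_drugs) for j in range(i + 1, n_drugs)]
    chosen = rng_pairs.choice(len(all_pairs), size=cfg.n_pairs, replace=False)
    pairs = [
        (universe.drug_ids[all_pairs[c][0]], universe.drug_ids[all_pairs[c][1]])
        for c in sorted(chosen.tolist())
    ]

    levels = rng_tox.choice(3, size=cfg.n_pairs, p=list(cfg.toxicity_marginals))
    if cfg.metric_toxicity_trend != 0.0:
        vals = np.array(
            [np.nan if (v := _pair_metric_value(universe, cfg, a, b)) is None else v for a, b in pairs]
        )
        have = ~np.isnan(vals)
        if have.sum() >= 3:
            levels = levels.copy()
            levels[have] = _copula_labels(
                vals[have], cfg.metric_toxicity_trend, cfg.toxicity_marginals, rng_tox
            )

    # standardized toxicity drives the synergy location shift
    z = (levels - levels.mean()) / (levels.std() if levels.std() > 0 else 1.0)

    lo_cl, hi_cl = cfg.cell_lines_range
    n_cl = rng_syn.integers(lo_cl, hi_cl + 1, size=cfg.n_pairs)
    pair_idx = np.repeat(np.arange(cfg.n_pairs), n_cl)
    cl_idx = np.concatenate([np.arange(c) for c in n_cl])
    loc = z[pair_idx] * cfg.synergy_toxicity_trend
    eps = cfg.noise_sd * rng_syn.standard_normal((len(pair_idx), len(SYNERGY_SCORES)))
    synergy = pd.DataFrame(
        {
            "drug_a": [universe.display_names[pairs[i][0]] for i in pair_idx],
            "drug_b": [universe.display_names[pairs[i][1]] for i in pair_idx],
            "cell_line": [f"CL-{c:02d}" for c in cl_idx],
            **{s: loc + eps[:, k] for k, s in enumerate(SYNERGY_SCORES)},
        }
    )

    dd_levels = levels.copy()
    if cfg.db_disagreement > 0:
        redraw = rng_dd.random(cfg.n_pairs) < cfg.db_disagreement
        dd_levels[redraw] = rng_dd.choice(3, size=int(redraw.sum()), p=list(cfg.toxicity_marginals))

    tox_db = pd.DataFrame(
        {
            "drug1": [universe.display_names[a] for a, _ in pairs],
            "drug2": [universe.display_names[b] for _, b in pairs],
            "level": levels.astype(int),
        }
    )
    tox_dd = pd.DataFrame(
        {
            "drug1": tox_db["drug1"],
            "drug2": tox_db["drug2"],
            "severity": [SEVERITY_LABELS[v] for v in dd_levels],
        }
    )
    labels = {canonical_pair(a, b): Severity(int(v)) for (a, b), v in zip(pairs, levels)}
    labels_dd = {canonical_pair(a, b): Severity(int(v)) for (a, b), v in zip(pairs, dd_levels)}
    return ObservationBundle(
        synergy=synergy,
        toxicity_drugbank=tox_db,
        toxicity_ddinter=tox_dd,
        labels=labels,
        labels_ddinter=labels_dd,
    )


def write_universe(universe: Universe, out_dir: str | Path) -> dict[str, Path]:
    """Emit the universe as files readable by the data_io loaders."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": out / "drugs.csv",
        "targets": out / "targets.csv",
        "pathways_lowest": out / "pathways_lowest.tsv",
        "pathways_all": out / "pathways_all.tsv",
        "network": out / "network_edges.txt",
        "id_map": out / "id_map.tsv",
    }
    pd.DataFrame(
        {
            "drug": [universe.display_names[d] for d in universe.drug_ids],
            "smiles": [universe.smiles.get(d, "") for d in universe.drug_ids],
        }
    ).to_csv(paths["drugs"], index=False)
    tgt_rows = [
        {"drug": universe.display_names[d], "protein": p}
        for d in universe.drug_ids
        for p in sorted(universe.targets[d])
    ]
    pd.DataFrame(tgt_rows).to_csv(paths["targets"], index=False)

    for key, view in (("pathways_lowest", universe.hierarchy.lowest), ("pathways_all", universe.hierarchy.all)):
        with open(paths[key], "w") as fh:
            for protein in sorted(view):
                for pw in sorted(view[protein]):
                    fh.write(f"{protein}\t{pw}\t{pw} pathway\t{SPECIES}\n")

    with open(paths["network"], "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v in sorted(map(sorted, universe.network.graph.edges)):
            fh.write(f"{u} {v} 900\n")
    with open(paths["id_map"], "w") as fh:
        fh.write("uniprot\tnode\n")
        for protein in sorted(universe.network.id_map):
            fh.write(f"{protein}\t{universe.network.id_map[protein]}\n")
    return paths


def write_observations(bundle: ObservationBundle, out_dir: str | Path) -> dict[str, Path]:
    """Emit the synergy table and both toxicity-dialect files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "synergy": out / "synergy.csv",
        "toxicity_drugbank": out / "toxicity_drugbank.csv",
        "toxicity_ddinter": out / "toxicity_ddinter.csv",
    }
    bundle.synergy.to_csv(paths["synergy"], index=False)
    bundle.toxicity_drugbank.to_csv(paths["toxicity_drugbank"], index=False)
    bundle.toxicity_ddinter.to_csv(paths["toxicity_ddinter"], index=False)
    return paths


def bundle_to_dataset(universe: Universe, bundle: ObservationBundle, sources: tuple[str, ...] = ("drugbank", "ddinter")):
    """Assemble an AnalysisDataset directly from in-memory simulation output."""
    from .data_io import assemble_dataset
    from .datatypes import ComboObservation, ToxicityLabel

    observations = [
        ComboObservation(
            drug_a=normalize_name(row.drug_a),
            drug_b=normalize_name(row.drug_b),
            cell_line=row.cell_line,
            synergy={s: float(getattr(row, s)) for s in SYNERGY_SCORES},
        )
        for row in bundle.synergy.itertuples()
    ]
    tox_maps = {}
    if "drugbank" in sources:
        tox_maps["drugbank"] = {
            p: ToxicityLabel(level=lvl, source="drugbank") for p, lvl in bundle.labels.items()
        }
    if "ddinter" in sources:
        tox_maps["ddinter"] = {
            p: ToxicityLabel(level=lvl, source="ddinter") for p, lvl in bundle.labels_ddinter.items()
        }
    return assemble_dataset(
        observations,
        tox_maps,
        targets=universe.targets,
        smiles=universe.smiles,
        provenance={"generator": "synthetic"},
    )
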