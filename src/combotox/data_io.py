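"""Readers for the external file dialects and dataset assembly.

Five input families are harmonized into the shared data model:

* synergy summary tables (DrugComb-style or the package's synthetic dialect),
* pairwise DDI severity tables (DrugBank-style numeric 0/1/2, DDInter-style
  Minor/Moderate/Major words, or synthetic),
* drug -> protein target long tables,
* protein -> pathway mappings in two hierarchy views (lowest / all levels),
* a PPIN edge list with an external-ID -> node mapping.

Assembly applies the study filter: keep only combinations present in both a
synergy source and at least one toxicity source, logging counts per source.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import pandas as pd

from .datatypes import (
    SYNERGY_SCORES,
    AnalysisDataset,
    ComboObservation,
    DrugRecord,
    Severity,
    ToxicityLabel,
    canonical_pair,
    normalize_name,
)
from .network_metrics import InteractionNetwork
from .similarity_metrics import PathwayHierarchy

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]

#: per-dialect column layout for synergy tables
SYNERGY_DIALECTS: dict[str, dict[str, str]] = {
    "synthetic": {
        "drug_a": "drug_a",
        "drug_b": "drug_b",
        "cell_line": "cell_line",
        **{s: s for s in SYNERGY_SCORES},
    },
    "drugcomb": {
        "drug_a": "drug_row",
        "drug_b": "drug_col",
        "cell_line": "cell_line_name",
        "bliss": "synergy_bliss",
        "hsa": "synergy_hsa",
        "loewe": "synergy_loewe",
        "zip": "synergy_zip",
        "s_max": "S_max",
        "s_mean": "S_mean",
        "s_sum": "S_sum",
    },
}


class FormatError(ValueError):
    """A required column or structural element is missing from an input file."""


def _apply_synonyms(name: str, synonyms: Optional[Mapping[str, str]]) -> str:
    if synonyms:
        return synonyms.get(name, synonyms.get(normalize_name(name), name))
    return name


def load_synergy_table(
    path: str | Path,
    dialect: str = "synthetic",
    column_map: Optional[Mapping[str, str]] = None,
    synonyms: Optional[Mapping[str, str]] = None,
) -> list[ComboObservation]:
    """Read a synergy summary table: one observation per (A, B, cell line) row.

    Drug names are normalized and the pair canonicalized; unparseable or blank
    score cells are recorded as absent (never zero) with a row-level warning.
    """
    if dialect not in SYNERGY_DIALECTS:
        raise ValueError(f"unknown synergy dialect: {dialect!r}")
    cols = dict(SYNERGY_DIALECTS[dialect])
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype=str)
    for key in ("drug_a", "drug_b", "cell_line"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing mandatory column {cols[key]!r} in {path}")
    score_cols = {s: cols[s] for s in SYNERGY_SCORES if cols[s] in df.columns}
    if not score_cols:
        raise FormatError(f"no synergy score columns found in {path}")

    observations = []
    for row_idx, row in df.iterrows():
        a = normalize_name(_apply_synonyms(str(row[cols["drug_a"]]), synonyms))
        b = normalize_name(_apply_synonyms(str(row[cols["drug_b"]]), synonyms))
        synergy: dict[str, float] = {}
        for score, col in score_cols.items():
            cell = row[col]
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
                continue
            try:
                synergy[score] = float(cell)
            except ValueError:
                logger.warning("row %d: unparseable %s value %r, recorded absent", row_idx, score, cell)
        observations.append(
            ComboObservation(drug_a=a, drug_b=b, cell_line=str(row[cols["cell_line"]]), synergy=synergy)
        )
    return observations


_TOXICITY_COLUMNS = {
    "drugbank": ("drug1", "drug2", "level"),
    "ddinter": ("drug1", "drug2", "severity"),
    "synthetic": ("drug_a", "drug_b", "level"),
}


def load_toxicity_table(
    path: str | Path,
    dialect: str,
    duplicate_policy: str = "max",
    synonyms: Optional[Mapping[str, str]] = None,
) -> dict[PairKey, ToxicityLabel]:
    """Read pairwise DDI severity into a canonical-pair -> label map.

    DrugBank-style files carry numeric levels 0/1/2; DDInter-style files carry
    the words Minor/Moderate/Major (other categories, e.g. Unknown, are dropped
    with a logged count). Duplicate entries for a pair are resolved by the
    maximum severity (clinically precautionary) under the default policy;
    ``duplicate_policy="first"`` keeps the first occurrence instead.
    """
    if dialect not in _TOXICITY_COLUMNS:
        raise ValueError(f"unknown toxicity dialect: {dialect!r}")
    c1, c2, cs = _TOXICITY_COLUMNS[dialect]
    df = pd.read_csv(path, dtype=str)
    for col in (c1, c2, cs):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    source = "synthetic" if dialect == "synthetic" else dialect
    out: dict[PairKey, ToxicityLabel] = {}
    dropped = conflicts = 0
    for _, row in df.iterrows():
        token = str(row[cs]).strip()
        try:
            if dialect == "ddinter":
                level = Severity.from_word(token)
            else:
                level = Severity(int(token))
        except (ValueError, KeyError):
            dropped += 1
            continue
        a = normalize_name(_apply_synonyms(str(row[c1]), synonyms))
        b = normalize_name(_apply_synonyms(str(row[c2]), synonyms))
        pair = canonical_pair(a, b)
        if pair in out and out[pair].level != level:
            conflicts += 1
            if duplicate_policy == "max":
                level = max(level, out[pair].level)
            elif duplicate_policy == "first":
                level = out[pair].level
            else:
                raise ValueError(f"unknown duplicate policy: {duplicate_policy!r}")
        out[pair] = ToxicityLabel(level=level, source=source)
    if dropped:
        logger.warning("%s: dropped %d rows with unrecognized severity tokens", path, dropped)
    if conflicts:
        logger.info("%s: resolved %d conflicting duplicate pairs (%s policy)", path, conflicts, duplicate_policy)
    if not out:
        raise FormatError(f"{path}: no usable severity rows after filtering")
    return out


def load_targets(
    path: str | Path,
    strip_isoforms: bool = True,
    synonyms: Optional[Mapping[str, str]] = None,
) -> dict[str, frozenset[str]]:
    """Read a (drug, protein) long table into per-drug target sets."""
    df = pd.read_csv(path, dtype=str)
    if not {"drug", "protein"} <= set(df.columns):
        raise FormatError(f"targets file {path} needs 'drug' and 'protein' columns")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        drug = normalize_name(_apply_synonyms(str(row["drug"]), synonyms))
        protein = str(row["protein"]).strip()
        if strip_isoforms and "-" in protein:
            protein = protein.split("-", 1)[0]
        out.setdefault(drug, set()).add(protein)
    return {d: frozenset(s) for d, s in out.items()}


def _read_pathway_file(path: str | Path, species_filter: str) -> dict[str, set[str]]:
    # headerless TSV: uniprot, pathway ID, pathway name, species
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"pathway file {path} needs >= 4 tab-separated columns")
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        if str(row.iloc[3]).strip() != species_filter:
            continue
        mapping.setdefault(str(row.iloc[0]).strip(), set()).add(str(row.iloc[1]).strip())
    return mapping


def load_pathways(
    lowest_path: str | Path,
    all_path: str | Path,
    species_filter: str = "Homo sapiens",
) -> PathwayHierarchy:
    """Read the lowest-level and all-level protein -> pathway mappings.

    The all-level view must be a superset of the lowest view per protein; a
    protein violating that (present in lowest but with extra pathways missing
    from all) is logged and the union is taken.
    """
    lowest = _read_pathway_file(lowest_path, species_filter)
    all_ = _read_pathway_file(all_path, species_filter)
    inconsistent = 0
    for protein, leafs in lowest.items():
        if not leafs <= all_.get(protein, set()):
            inconsistent += 1
            all_.setdefault(protein, set()).update(leafs)
    if inconsistent:
        logger.warning("%d proteins had lowest-level pathways missing from the all-level view; union taken", inconsistent)
    return PathwayHierarchy(
        lowest={p: frozenset(s) for p, s in lowest.items()},
        all={p: frozenset(s) for p, s in all_.items()},
    )


def load_network(
    edges_path: str | Path,
    id_map_path: str | Path,
    min_edge_score: int = 0,
) -> InteractionNetwork:
    """Read a STRING-style edge list and UniProt -> node-ID map.

    Edges scoring below ``min_edge_score`` are dropped; the graph is
    undirected and simple. ID-map collisions keep the first mapping with a
    warning; unmapped graph nodes are allowed.
    """
    edges = pd.read_csv(edges_path, sep=r"\s+", dtype=str)
    need = {"protein1", "protein2"}
    if not need <= set(edges.columns):
        raise FormatError(f"edge list {edges_path} needs 'protein1' and 'protein2' columns")
    g = nx.Graph()
    for _, row in edges.iterrows():
        score = int(float(row["combined_score"])) if "combined_score" in edges.columns else 0
        if score < min_edge_score:
            continue
        u, v = str(row["protein1"]), str(row["protein2"])
        if u != v:
            g.add_edge(u, v)

    idmap_df = pd.read_csv(id_map_path, sep="\t", dtype=str)
    if not {"uniprot", "node"} <= set(idmap_df.columns):
        raise FormatError(f"id map {id_map_path} needs 'uniprot' and 'node' columns")
    id_map: dict[str, str] = {}
    collisions = 0
    for _, row in idmap_df.iterrows():
        u = str(row["uniprot"]).strip()
        if u in id_map:
            collisions += 1
            continue
        id_map[u] = str(row["node"]).strip()
    if collisions:
        logger.warning("%s: %d id-map collisions, first mapping kept", id_map_path, collisions)
    unmapped = sum(1 for node in id_map.values() if node not in g)
    if unmapped:
        logger.info("%d mapped proteins point at nodes absent from the graph", unmapped)
    return InteractionNetwork(graph=g, id_map=id_map)


def assemble_dataset(
    observations: list[ComboObservation],
    toxicity_maps: Mapping[str, Mapping[PairKey, ToxicityLabel]],
    targets: Optional[Mapping[str, frozenset[str]]] = None,
    smiles: Optional[Mapping[str, str]] = None,
    provenance: Optional[dict] = None,
) -> AnalysisDataset:
    """Join synergy observations with toxicity labels and drug annotations.

    An observation is retained when at least one toxicity source labels its
    pair; per-source analyses subset later. The filter log (counts before and
    after, per source) is recorded in the dataset provenance.
    """
    targets = targets or {}
    smiles = smiles or {}
    n_in = len(observations)
    kept: list[ComboObservation] = []
    per_source = {src: 0 for src in toxicity_maps}
    for obs in observations:
        labels = {}
        for src, tmap in toxicity_maps.items():
            label = tmap.get(obs.pair)
            if label is not None:
                labels[src] = label
                per_source[src] += 1
        if labels and obs.synergy:
            obs.toxicity = labels
            kept.append(obs)
    if not kept:
        raise ValueError("no observations survive the toxicity/synergy join")

    drug_ids = sorted({d for obs in kept for d in obs.pair})
    drugs = {
        d: DrugRecord(
            drug_id=d,
            name=d,
            smiles=smiles.get(d),
            targets=frozenset(targets.get(d, frozenset())),
        )
        for d in drug_ids
    }
    prov = dict(provenance or {})
    prov["filter_log"] = {
        "observations_in": n_in,
        "observations_kept": len(kept),
        "labelled_rows_per_source": per_source,
    }
    ds = AnalysisDataset(drugs=drugs, observations=kept, provenance=prov)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# tidy export / round-trip

def write_dataset(dataset: AnalysisDataset, out_dir: str | Path) -> None:
    """Write the tidy TSV export: observations, drugs, and a JSON provenance log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs_rows = []
    for obs in dataset.observations:
        row: dict = {"drug_a": obs.drug_a, "drug_b": obs.drug_b, "cell_line": obs.cell_line}
        for s in SYNERGY_SCORES:
            row[s] = obs.synergy.get(s, "")
        for src in sorted({src for o in dataset.observations for src in o.toxicity}):
            label = obs.toxicity.get(src)
            row[f"toxicity_{src}"] = "" if label is None else int(label.level)
        obs_rows.append(row)
    pd.DataFrame(obs_rows).to_csv(out / "observations.tsv", sep="\t", index=False)

    drug_rows = [
        {
            "drug_id": d.drug_id,
            "name": d.name,
            "smiles": d.smiles or "",
            "targets": ";".join(sorted(d.targets)),
        }
        for d in (dataset.drugs[k] for k in sorted(dataset.drugs))
    ]
    pd.DataFrame(drug_rows).to_csv(out / "drugs.tsv", sep="\t", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(dataset.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_dataset(in_dir: str | Path) -> AnalysisDataset:
    """Re-read a tidy export written by :func:`write_dataset`."""
    indir = Path(in_dir)
    obs_df = pd.read_csv(indir / "observations.tsv", sep="\t", dtype=str)
    tox_cols = [c for c in obs_df.columns if c.startswith("toxicity_")]
    observations = []
    for _, row in obs_df.iterrows():
        synergy = {
            s: float(row[s])
            for s in SYNERGY_SCORES
            if s in obs_df.columns and isinstance(row[s], str) and row[s].strip() != ""
        }
        toxicity = {}
        for col in tox_cols:
            cell = row[col]
            if isinstance(cell, str) and cell.strip() != "":
                src = col[len("toxicity_"):]
                toxicity[src] = ToxicityLabel(level=Severity(int(cell)), source=src)
        observations.append(
            ComboObservation(
                drug_a=row["drug_a"],
                drug_b=row["drug_b"],
                cell_line=row["cell_line"],
                synergy=synergy,
                toxicity=toxicity,
            )
        )
    drugs_df = pd.read_csv(indir / "drugs.tsv", sep="\t", dtype=str).fillna("")
    drugs = {}
    for _, row in drugs_df.iterrows():
        targets = frozenset(t for t in str(row["targets"]).split(";") if t)
        drugs[row["drug_id"]] = DrugRecord(
            drug_id=row["drug_id"],
            name=row["name"],
            smiles=row["smiles"] or None,
            targets=targets,
        )
    with open(indir / "provenance.json") as fh:
        provenance = json.load(fh)
    ds = AnalysisDataset(drugs=drugs, observations=observations, provenance=provenance)
    ds.validate()
    return ds
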