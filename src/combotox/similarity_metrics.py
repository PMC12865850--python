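"""Per-pair overlap and structural similarity metrics.

Jaccard overlap of target sets and of Reactome-style pathway sets (lowest-level
and all-level hierarchy views), and Tanimoto similarity of Morgan fingerprint
bit vectors. On bit vectors the Tanimoto coefficient
A.B / (|A|^2 + |B|^2 - A.B) is identical to the Jaccard index of the on-bit
sets, which the test suite checks exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .datatypes import AnalysisDataset
from .network_metrics import InteractionNetwork, avg_target_distance, neighbor_jaccard

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "target_jaccard",
    "pathway_jaccard_lowest",
    "pathway_jaccard_all",
    "tanimoto",
    "avg_target_distance",
    "neighbor_jaccard",
)


def jaccard(set_a: Set, set_b: Set) -> float:
    """|A n B| / |A u B|; both empty -> 0.0 by convention."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


@dataclass
class PathwayHierarchy:
    """Per-protein pathway membership under two hierarchy views.

    ``lowest`` maps a protein to its leaf-level pathways only; ``all`` to
    every pathway on the path to the hierarchy root. For any protein,
    all >= lowest (superset).
    """

    lowest: dict[str, frozenset[str]]
    all: dict[str, frozenset[str]]

    def view(self, name: str) -> dict[str, frozenset[str]]:
        if name == "lowest":
            return self.lowest
        if name == "all":
            return self.all
        raise ValueError(f"unknown hierarchy view: {name!r}")


def pathway_sets(targets: Set[str], hierarchy: PathwayHierarchy, view: str) -> frozenset[str]:
    """Union over targets of each protein's pathway set under the given view."""
    mapping = hierarchy.view(view)
    out: set[str] = set()
    for t in targets:
        out |= mapping.get(t, frozenset())
    return frozenset(out)


@dataclass
class Fingerprint:
    """Fixed-length binary Morgan (circular substructure) fingerprint."""

    bits: np.ndarray  # uint8 vector of 0/1
    n_bits: int
    radius: int

    def on_bits(self) -> frozenset[int]:
        return frozenset(int(i) for i in np.flatnonzero(self.bits))


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Optional[Fingerprint]:
    """Hashed Morgan fingerprint of a SMILES string; None (with a warning) if unparseable."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        logger.warning("unparseable SMILES %r; structural similarity will be absent", smiles)
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return Fingerprint(bits=arr, n_bits=n_bits, radius=radius)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient on binary vectors; both all-zero -> 0.0."""
    if fp_a.n_bits != fp_b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {fp_a.n_bits} vs {fp_b.n_bits}")
    a = fp_a.bits.astype(np.int64)
    b = fp_b.bits.astype(np.int64)
    ab = int(np.dot(a, b))
    denom = int(np.dot(a, a)) + int(np.dot(b, b)) - ab
    if denom == 0:
        return 0.0
    return ab / denom


def compute_pair_metrics(
    dataset: AnalysisDataset,
    hierarchy: Optional[PathwayHierarchy] = None,
    network: Optional[InteractionNetwork] = None,
    which: Iterable[str] = METRIC_NAMES,
    fp_radius: int = 2,
    fp_bits: int = 2048,
    unreachable: str = "exclude",
    fingerprints: Optional[Mapping[str, Optional[Fingerprint]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """One row of similarity/distance metrics per distinct canonical pair.

    Metrics whose inputs are missing for a pair (no targets, no parseable
    SMILES, no mappable network nodes) are left absent (NaN), never zero;
    a tally of absence reasons is returned alongside the table. Metrics are
    cell-line independent, so each pair is computed once.
    """
    which = list(which)
    unknown = set(which) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics requested: {sorted(unknown)}")
    pairs = dataset.pairs()
    if not pairs:
        raise ValueError("no pairs to compute metrics for")
    need_hier = {"pathway_jaccard_lowest", "pathway_jaccard_all"} & set(which)
    if need_hier and hierarchy is None:
        raise ValueError("pathway metrics requested but no hierarchy supplied")
    need_net = {"avg_target_distance", "neighbor_jaccard"} & set(which)
    if need_net and network is None:
        raise ValueError("network metrics requested but no network supplied")

    fps: dict[str, Optional[Fingerprint]] = dict(fingerprints or {})
    if "tanimoto" in which and fingerprints is None:
        for drug_id in sorted({d for p in pairs for d in p}):
            rec = dataset.drugs.get(drug_id)
            fps[drug_id] = (
                morgan_fingerprint(rec.smiles, fp_radius, fp_bits)
                if rec is not None and rec.smiles
                else None
            )

    absence: dict[str, int] = {m: 0 for m in which}
    rows = []
    for a, b in pairs:
        ta = dataset.drugs[a].targets
        tb = dataset.drugs[b].targets
        row: dict = {"drug_a": a, "drug_b": b}
        for m in which:
            val: Optional[float] = None
            if m == "target_jaccard":
                if ta and tb:
                    val = jaccard(ta, tb)
            elif m in ("pathway_jaccard_lowest", "pathway_jaccard_all"):
                if ta and tb:
                    view = "lowest" if m.endswith("lowest") else "all"
                    val = jaccard(
                        pathway_sets(ta, hierarchy, view),
                        pathway_sets(tb, hierarchy, view),
                    )
            elif m == "tanimoto":
                fa, fb = fps.get(a), fps.get(b)
                if fa is not None and fb is not None:
                    val = tanimoto(fa, fb)
            elif m == "avg_target_distance":
                val = avg_target_distance(ta, tb, network, unreachable=unreachable)
            elif m == "neighbor_jaccard":
                val = neighbor_jaccard(ta, tb, network, k=2)
            if val is None:
                absence[m] += 1
            row[m] = np.nan if val is None else val
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, {"n_pairs": len(pairs), "absent": absence}
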