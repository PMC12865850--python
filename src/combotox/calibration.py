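"""Simulation studies validating the statistical battery and the generator.

These are the package's own quality-control experiments: type-I error
calibration of the nonparametric tests, power / effect-size recovery of the
Jonckheere-Terpstra trend test against planted couplings, the directional
sign-flip scenario, independence behaviour of the correlation suite, and
end-to-end byte determinism. They are exercised by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import data_io, pipeline
from .similarity_metrics import compute_pair_metrics
from .synthetic_data import (
    SimConfig,
    bundle_to_dataset,
    simulate_observations,
    simulate_universe,
    write_observations,
    write_universe,
)
from .trend_stats import OrderedGroups, dunn_posthoc, jonckheere_terpstra, kruskal_wallis


def null_rejection_rates(
    n_sims: int = 10000,
    n_per_group: int = 30,
    k: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical type-I error of KW, per-contrast Dunn (pre-correction), and JT.

    All groups are drawn from the same normal distribution, so every rejection
    is a false positive; a calibrated test rejects at ~alpha.
    """
    rng = np.random.default_rng(seed)
    rej = {"kruskal_wallis": 0, "dunn": 0, "jonckheere_terpstra": 0}
    n_dunn = 0
    for _ in range(n_sims):
        g = OrderedGroups(list(rng.standard_normal((k, n_per_group))))
        if kruskal_wallis(g).p_value < alpha:
            rej["kruskal_wallis"] += 1
        for res in dunn_posthoc(g):
            # pre-correction two-sided p, from the z statistic
            if 2.0 * stats.norm.sf(abs(res.statistic)) < alpha:
                rej["dunn"] += 1
            n_dunn += 1
        if jonckheere_terpstra(g, alternative="increasing").p_value < alpha:
            rej["jonckheere_terpstra"] += 1
    return {
        "kruskal_wallis": rej["kruskal_wallis"] / n_sims,
        "dunn": rej["dunn"] / n_dunn,
        "jonckheere_terpstra": rej["jonckheere_terpstra"] / n_sims,
    }


def _pipeline_jt(cfg: SimConfig, universe, score: str = "bliss") -> tuple[float, float]:
    """Increasing-direction JT (p, r) from the full pipeline on one simulation."""
    bundle = simulate_observations(cfg, universe)
    dataset = bundle_to_dataset(universe, bundle, sources=("drugbank",))
    report = pipeline.analyze_synergy_vs_toxicity(dataset, scores=[score], sources=["drugbank"])
    inc = report.trend[report.trend.direction == "increasing"]
    return float(inc.p.iloc[0]), float(inc.effect.iloc[0])


def jt_trend_recovery(
    couplings: Sequence[float] = (0.0, 0.1, 0.3, 0.5),
    n_seeds: int = 200,
    n_pairs: int = 3000,
    n_drugs: int = 150,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> dict[float, dict[str, float]]:
    """Power and effect-size recovery of the pipeline's JT test vs planted coupling.

    For each planted synergy<->toxicity rank coupling, runs `n_seeds` full
    simulate -> assemble -> analyze passes and reports the fraction of seeds
    with a significant increasing trend (and r > 0), plus the mean estimated r.
    """
    universe = simulate_universe(SimConfig(n_drugs=n_drugs, n_pairs=n_pairs, seed=base_seed))
    out = {}
    for coupling in couplings:
        hits, rs = 0, []
        for rep in range(n_seeds):
            cfg = SimConfig(
                n_drugs=n_drugs,
                n_pairs=n_pairs,
                synergy_toxicity_trend=coupling,
                seed=base_seed + 1 + rep,
            )
            p, r = _pipeline_jt(cfg, universe)
            rs.append(r)
            if p < alpha and r > 0:
                hits += 1
        out[coupling] = {"power": hits / n_seeds, "mean_r": float(np.mean(rs))}
    return out


def jt_signflip(
    coupling: float = -0.5,
    n_pairs: int = 800,
    n_drugs: int = 80,
    n_proteins: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Plant a negative avg-target-distance <-> severity coupling; JT should flag
    the decreasing direction only (severe pairs sit closer on the network)."""
    cfg = SimConfig(
        n_drugs=n_drugs,
        n_proteins=n_proteins,
        n_pairs=n_pairs,
        metric_toxicity_trend=coupling,
        coupling_metric="avg_target_distance",
        seed=seed,
    )
    universe = simulate_universe(cfg)
    bundle = simulate_observations(cfg, universe)
    dataset = bundle_to_dataset(universe, bundle, sources=("drugbank",))
    table, _ = compute_pair_metrics(
        dataset, network=universe.network, which=["avg_target_distance"]
    )
    report = pipeline.analyze_overlap_vs_toxicity(
        dataset, table, sources=["drugbank"], metrics=["avg_target_distance"]
    )
    tr = report.trend
    return {
        "p_decreasing": float(tr[tr.direction == "decreasing"].p.iloc[0]),
        "p_increasing": float(tr[tr.direction == "increasing"].p.iloc[0]),
    }


def independence_correlations(
    n_pairs: int = 10000,
    n_drugs: int = 150,
    seed: int = 0,
) -> dict[str, float]:
    """Max |Pearson r| and R^2 over (synergy score x overlap metric) when synergy
    is simulated independently of every metric (all couplings zero)."""
    cfg = SimConfig(n_drugs=n_drugs, n_pairs=n_pairs, synergy_toxicity_trend=0.0, seed=seed)
    universe = simulate_universe(cfg)
    bundle = simulate_observations(cfg, universe)
    dataset = bundle_to_dataset(universe, bundle, sources=("drugbank",))
    table, _ = compute_pair_metrics(
        dataset,
        hierarchy=universe.hierarchy,
        which=["target_jaccard", "pathway_jaccard_lowest", "pathway_jaccard_all"],
    )
    report = pipeline.analyze_overlap_vs_synergy(dataset, table)
    corr = report.correlations.dropna(subset=["pearson_r"])
    return {
        "max_abs_pearson_r": float(corr.pearson_r.abs().max()),
        "max_r_squared": float(corr.r_squared.max()),
    }


def _hash_dir(path: Path) -> dict[str, str]:
    out = {}
    for f in sorted(path.rglob("*")):
        if f.is_file():
            out[str(f.relative_to(path))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


def run_end_to_end(cfg: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """simulate -> write files -> ingest -> metrics -> analyze -> report; returns file hashes."""
    out = Path(out_dir)
    sim_dir, data_dir, report_dir = out / "sim", out / "dataset", out / "report"
    universe = simulate_universe(cfg)
    bundle = simulate_observations(cfg, universe)
    paths = write_universe(universe, sim_dir)
    paths.update(write_observations(bundle, sim_dir))

    observations = data_io.load_synergy_table(paths["synergy"], dialect="synthetic")
    tox_maps = {
        "drugbank": data_io.load_toxicity_table(paths["toxicity_drugbank"], dialect="drugbank"),
        "ddinter": data_io.load_toxicity_table(paths["toxicity_ddinter"], dialect="ddinter"),
    }
    targets = data_io.load_targets(paths["targets"])
    import pandas as pd

    drugs_df = pd.read_csv(paths["drugs"], dtype=str).fillna("")
    from .datatypes import normalize_name

    smiles = {normalize_name(r["drug"]): r["smiles"] for _, r in drugs_df.iterrows() if r["smiles"]}
    dataset = data_io.assemble_dataset(observations, tox_maps, targets=targets, smiles=smiles)
    data_io.write_dataset(dataset, data_dir)

    hierarchy = data_io.load_pathways(paths["pathways_lowest"], paths["pathways_all"])
    network = data_io.load_network(paths["network"], paths["id_map"])
    table, _ = compute_pair_metrics(dataset, hierarchy=hierarchy, network=network)
    table.to_csv(data_dir / "pair_metrics.tsv", sep="\t", index=False, float_format="%.10g")

    report = pipeline.analyze_synergy_vs_toxicity(dataset, scores=["bliss", "zip"], n_min=5)
    report = report.merge(pipeline.analyze_overlap_vs_toxicity(dataset, table, n_min=5))
    report = report.merge(pipeline.analyze_toxicity_scores(dataset, table, n_min=5))
    report = report.merge(pipeline.analyze_overlap_vs_synergy(dataset, table, scores=["bliss", "zip"]))
    pipeline.write_report(report, report_dir)
    return _hash_dir(out)


def end_to_end_determinism(seed: int, work_dir: str | Path, **cfg_kw) -> bool:
    """Two identical full runs must produce byte-identical file trees."""
    cfg_kw.setdefault("n_drugs", 40)
    cfg_kw.setdefault("n_proteins", 100)
    cfg_kw.setdefault("n_pairs", 250)
    work = Path(work_dir)
    h1 = run_end_to_end(SimConfig(seed=seed, **cfg_kw), work / "run1")
    h2 = run_end_to_end(SimConfig(seed=seed, **cfg_kw), work / "run2")
    return h1 == h2
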