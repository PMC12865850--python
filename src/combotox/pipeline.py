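"""End-to-end analyses: synergy vs toxicity, overlap vs toxicity, overlap vs synergy.

Each analyzed variable gets the full nonparametric battery — normality screen,
Kruskal-Wallis omnibus with eta^2, Dunn post-hoc (Bonferroni) with Cliff's
delta for the three severity contrasts, and Jonckheere-Terpstra in both trend
directions — emitted as tidy tables. The battery always runs regardless of the
normality screen's outcome (the screen is reported, never used to switch to a
parametric test). Cells with too little data are explicit rows with a reason
code, never silent omissions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SEVERITY_LABELS, SYNERGY_SCORES, AnalysisDataset, Severity
from .trend_stats import (
    OrderedGroups,
    correlation_suite,
    dunn_posthoc,
    jonckheere_terpstra,
    kruskal_wallis,
    normality_test,
)

OVERLAP_METRICS = ("target_jaccard", "pathway_jaccard_lowest", "pathway_jaccard_all")
TOXICITY_SCORE_METRICS = ("tanimoto", "avg_target_distance", "neighbor_jaccard")


@dataclass
class AnalysisReport:
    proportions: pd.DataFrame = field(default_factory=pd.DataFrame)
    normality: pd.DataFrame = field(default_factory=pd.DataFrame)
    omnibus: pd.DataFrame = field(default_factory=pd.DataFrame)
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    trend: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    def merge(self, other: "AnalysisReport") -> "AnalysisReport":
        def cat(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
            if a.empty:
                return b.reset_index(drop=True)
            if b.empty:
                return a.reset_index(drop=True)
            return pd.concat([a, b], ignore_index=True)

        return AnalysisReport(
            proportions=cat(self.proportions, other.proportions),
            normality=cat(self.normality, other.normality),
            omnibus=cat(self.omnibus, other.omnibus),
            posthoc=cat(self.posthoc, other.posthoc),
            trend=cat(self.trend, other.trend),
            correlations=cat(self.correlations, other.correlations),
            provenance={**self.provenance, **other.provenance},
        )


def _severity_groups(values: np.ndarray, levels: np.ndarray) -> OrderedGroups:
    groups = [values[levels == lvl] for lvl in (0, 1, 2)]
    return OrderedGroups(groups, list(SEVERITY_LABELS))


def _row(test: str, variable: str, source: str, **kw) -> dict:
    base = {
        "test": test,
        "metric": variable,
        "source_db": source,
        "statistic": np.nan,
        "p": np.nan,
        "effect": np.nan,
        "effect_name": "",
        "direction": "",
        "n_minor": 0,
        "n_moderate": 0,
        "n_major": 0,
        "notes": "",
    }
    base.update(kw)
    return base


def _battery(
    variable: str,
    source: str,
    values: np.ndarray,
    levels: np.ndarray,
    n_min: int,
) -> AnalysisReport:
    """Run the full battery for one (variable, severity-source) cell."""
    rep = AnalysisReport()
    g = _severity_groups(values, levels)
    sizes = dict(zip(("n_minor", "n_moderate", "n_major"), g.sizes))

    reason = None
    if min(g.sizes) < n_min:
        reason = f"insufficient_data:group_below_{n_min}"
    elif np.ptp(values) == 0:
        reason = "insufficient_data:zero_variance"

    if reason is not None:
        rep.normality = pd.DataFrame([_row("dagostino_pearson", variable, source, notes=reason, **sizes)])
        rep.omnibus = pd.DataFrame([_row("kruskal_wallis", variable, source, notes=reason, **sizes)])
        rep.posthoc = pd.DataFrame(
            [
                _row("dunn", variable, source, notes=f"{a} vs {b}; {reason}", **sizes)
                for a, b in (("Minor", "Moderate"), ("Minor", "Major"), ("Moderate", "Major"))
            ]
        )
        rep.trend = pd.DataFrame(
            [
                _row("jonckheere_terpstra", variable, source, direction=d, notes=reason, **sizes)
                for d in ("increasing", "decreasing")
            ]
        )
        return rep

    norm = normality_test(values)
    rep.normality = pd.DataFrame(
        [_row("dagostino_pearson", variable, source, statistic=norm.statistic, p=norm.p_value, **sizes)]
    )
    kw = kruskal_wallis(g)
    rep.omnibus = pd.DataFrame(
        [
            _row(
                "kruskal_wallis", variable, source,
                statistic=kw.statistic, p=kw.p_value,
                effect=kw.effect_size, effect_name=kw.effect_name, direction=kw.direction, **sizes,
            )
        ]
    )
    rep.posthoc = pd.DataFrame(
        [
            _row(
                "dunn", variable, source,
                statistic=r.statistic, p=r.p_value, effect=r.effect_size,
                effect_name=r.effect_name, direction=r.direction, notes=r.notes, **sizes,
            )
            for r in dunn_posthoc(g)
        ]
    )
    rep.trend = pd.DataFrame(
        [
            _row(
                "jonckheere_terpstra", variable, source,
                statistic=r.statistic, p=r.p_value, effect=r.effect_size,
                effect_name=r.effect_name, direction=d, notes=r.notes, **sizes,
            )
            for d in ("increasing", "decreasing")
            for r in [jonckheere_terpstra(g, alternative=d)]
        ]
    )
    return rep


def _rows_for_source(dataset: AnalysisDataset, source: str) -> list:
    return [obs for obs in dataset.observations if source in obs.toxicity]


def analyze_synergy_vs_toxicity(
    dataset: AnalysisDataset,
    scores: Sequence[str] = SYNERGY_SCORES,
    sources: Sequence[str] = ("drugbank", "ddinter"),
    n_min: int = 20,
    synergistic_only: Optional[float] = None,
) -> AnalysisReport:
    """Battery + severity proportions per (synergy score, toxicity source).

    ``synergistic_only`` restricts the proportion panel to observations whose
    score exceeds the threshold (default: include all scored observations).
    """
    report = AnalysisReport()
    prop_rows = []
    for source in sources:
        obs = _rows_for_source(dataset, source)
        for score in scores:
            rows = [o for o in obs if score in o.synergy]
            values = np.array([o.synergy[score] for o in rows])
            levels = np.array([int(o.toxicity[source].level) for o in rows])
            sel = values > synergistic_only if synergistic_only is not None else np.ones(len(values), bool)
            n_sel = int(sel.sum())
            for lvl in (0, 1, 2):
                prop_rows.append(
                    {
                        "source_db": source,
                        "score": score,
                        "toxicity": SEVERITY_LABELS[lvl],
                        "fraction": float((levels[sel] == lvl).mean()) if n_sel else np.nan,
                        "n": n_sel,
                    }
                )
            report = report.merge(_battery(score, source, values, levels, n_min))
    report.proportions = pd.DataFrame(prop_rows)
    return report


def _metric_values_per_row(
    dataset: AnalysisDataset, metric_table: pd.DataFrame, metric: str, source: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Broadcast a per-pair metric to (pair, cell line) rows labelled by `source`.

    Returns (values, severity levels, count of rows excluded for absent metric).
    """
    lookup = {
        (r.drug_a, r.drug_b): getattr(r, metric) for r in metric_table.itertuples()
    }
    vals, levels, absent = [], [], 0
    for obs in _rows_for_source(dataset, source):
        v = lookup.get(obs.pair, np.nan)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            absent += 1
            continue
        vals.append(float(v))
        levels.append(int(obs.toxicity[source].level))
    return np.array(vals), np.array(levels), absent


def analyze_overlap_vs_toxicity(
    dataset: AnalysisDataset,
    metric_table: pd.DataFrame,
    sources: Sequence[str] = ("drugbank", "ddinter"),
    metrics: Sequence[str] = OVERLAP_METRICS,
    n_min: int = 20,
) -> AnalysisReport:
    """Battery per (overlap metric, toxicity source); absent metrics excluded with counts."""
    report = AnalysisReport()
    excluded = {}
    for source in sources:
        for metric in metrics:
            if metric not in metric_table.columns:
                continue
            values, levels, absent = _metric_values_per_row(dataset, metric_table, metric, source)
            excluded[f"{source}:{metric}"] = absent
            if len(values) == 0:
                values, levels = np.array([0.0]), np.array([0])
            report = report.merge(_battery(metric, source, values, levels, n_min))
    report.provenance["excluded_absent_metric_rows"] = excluded
    return report


def analyze_toxicity_scores(
    dataset: AnalysisDataset,
    metric_table: pd.DataFrame,
    sources: Sequence[str] = ("drugbank", "ddinter"),
    n_min: int = 20,
) -> AnalysisReport:
    """Battery for the toxicity-penalty metrics (Tanimoto, avg target distance, neighbor Jaccard)."""
    present = [m for m in TOXICITY_SCORE_METRICS if m in metric_table.columns and metric_table[m].notna().any()]
    if not present:
        raise ValueError(
            f"none of the toxicity-score metrics {TOXICITY_SCORE_METRICS} are available in the metric table"
        )
    return analyze_overlap_vs_toxicity(dataset, metric_table, sources, metrics=present, n_min=n_min)


def analyze_overlap_vs_synergy(
    dataset: AnalysisDataset,
    metric_table: pd.DataFrame,
    scores: Sequence[str] = SYNERGY_SCORES,
    metrics: Sequence[str] = OVERLAP_METRICS,
) -> AnalysisReport:
    """Pearson/Spearman/R^2 of each synergy score against each overlap metric."""
    lookup = {m: {(r.drug_a, r.drug_b): getattr(r, m) for r in metric_table.itertuples()} for m in metrics if m in metric_table.columns}
    rows = []
    for score in scores:
        for metric in sorted(lookup):
            xs, ys = [], []
            for obs in dataset.observations:
                if score not in obs.synergy:
                    continue
                v = lookup[metric].get(obs.pair, np.nan)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                xs.append(float(v))
                ys.append(obs.synergy[score])
            row = {"score": score, "metric": metric, "n": len(xs)}
            if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
                row["notes"] = "insufficient_data"
                row.update(
                    {k: np.nan for k in ("pearson_r", "pearson_p", "spearman_rho", "spearman_p", "r_squared", "slope", "intercept")}
                )
            else:
                row.update(correlation_suite(xs, ys))
                row["notes"] = ""
            rows.append(row)
    rep = AnalysisReport()
    rep.correlations = pd.DataFrame(rows)
    return rep


REPORT_TABLES = ("proportions", "normality", "omnibus", "posthoc", "trend", "correlations")


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """Emit one TSV per table, a JSON bundle, and a short human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {}
    for name in REPORT_TABLES:
        df: pd.DataFrame = getattr(report, name)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        bundle[name] = json.loads(df.to_json(orient="records")) if not df.empty else []
    bundle["provenance"] = report.provenance
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["analysis summary", "================"]
    for name in REPORT_TABLES:
        df = getattr(report, name)
        lines.append(f"{name}: {len(df)} rows")
    if not report.trend.empty and "p" in report.trend:
        sig = report.trend[(report.trend["p"] < 0.05)]
        for r in sig.itertuples():
            lines.append(
                f"  trend {r.metric} [{r.source_db}] {r.direction}: p={r.p:.3g}, r={r.effect:.3f}"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
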