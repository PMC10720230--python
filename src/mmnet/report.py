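"""Population summaries and two-population comparison reports.

Descriptive statistics per cohort (per-capita diagnoses by age and
chapter, single-disease vs multimorbidity proportions, mean age), network
complexity ratios between populations, top-k comorbidity rankings, and
overlap analysis of patterns and hubs.

"Diagnoses" are counted as distinct 3-character codes per baseline record
(deduplicated), the same definition pattern enumeration uses, so per-capita
figures and pattern counts share one denominator convention.  Percentages
and ratios are reported to 2 decimal places with half-up rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import icd10
from .cohort import Cohort, stratify_by_sex
from .hubs import HubReport, hub_pipeline
from .network import edge_table, node_table, write_graphml
from .screening import PatternResult, patterns_to_frame

__all__ = [
    "ComparisonReport",
    "PopulationSummary",
    "complexity_ratio",
    "overlap_analysis",
    "round2",
    "run_full_comparison",
    "summarize_population",
    "top_k_comorbidities",
]


def round2(x: float) -> float:
    """Half-up rounding to 2 decimal places (print convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class PopulationSummary:
    """Descriptive statistics of one cohort."""

    label: str
    n_inpatients: int
    n_diseases: int
    n_diagnoses: int
    per_capita_diagnoses: float
    per_capita_by_age_chapter: pd.DataFrame  # index age, columns chapter
    single_disease_count: int
    single_disease_pct: float
    multimorbidity_count: int
    multimorbidity_pct: float
    multimorbidity_pct_by_age: pd.Series
    mean_age: float
    sd_age: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_inpatients": self.n_inpatients,
            "n_diseases": self.n_diseases,
            "n_diagnoses": self.n_diagnoses,
            "per_capita_diagnoses": round2(self.per_capita_diagnoses),
            "single_disease_count": self.single_disease_count,
            "single_disease_pct": round2(self.single_disease_pct),
            "multimorbidity_count": self.multimorbidity_count,
            "multimorbidity_pct": round2(self.multimorbidity_pct),
            "mean_age": round2(self.mean_age),
            "sd_age": round2(self.sd_age),
        }


def summarize_population(cohort: Cohort) -> PopulationSummary:
    """Per-capita diagnoses (overall and by age x chapter), multimorbidity %.

    A record with k distinct codes contributes k diagnoses; multimorbidity
    means >= 2 distinct diseases at baseline.  Per-capita by chapter sums
    over chapters to the overall per-capita at every age.
    """
    if cohort.n_inpatients == 0:
        raise ValueError("empty cohort")
    n = cohort.n_inpatients
    ages = np.array([rec.age for rec in cohort.records])
    k_codes = np.array([len(rec.codes) for rec in cohort.records])
    codes_seen: set[str] = set()
    by_age_chapter: dict[tuple[int, int], int] = {}
    for rec in cohort.records:
        codes_seen.update(rec.codes)
        for code in rec.codes:
            chap = icd10.chapter(code) or 0
            key = (rec.age, chap)
            by_age_chapter[key] = by_age_chapter.get(key, 0) + 1
    age_index = sorted({a for a, _ in by_age_chapter})
    chapters = sorted({c for _, c in by_age_chapter})
    age_counts = pd.Series(ages).value_counts()
    table = pd.DataFrame(0.0, index=age_index, columns=chapters)
    for (age, chap), count in by_age_chapter.items():
        table.loc[age, chap] = count / age_counts[age]
    multi_mask = k_codes >= 2
    multi_by_age = pd.Series(multi_mask).groupby(pd.Series(ages)).mean() * 100.0
    n_multi = int(multi_mask.sum())
    return PopulationSummary(
        label=cohort.label, n_inpatients=n, n_diseases=len(codes_seen),
        n_diagnoses=int(k_codes.sum()),
        per_capita_diagnoses=float(k_codes.sum() / n),
        per_capita_by_age_chapter=table,
        single_disease_count=n - n_multi,
        single_disease_pct=100.0 * (n - n_multi) / n,
        multimorbidity_count=n_multi,
        multimorbidity_pct=100.0 * n_multi / n,
        multimorbidity_pct_by_age=multi_by_age,
        mean_age=float(ages.mean()), sd_age=float(ages.std(ddof=1)),
    )


def complexity_ratio(network_a: nx.Graph, network_b: nx.Graph) -> float:
    """Edge-count ratio |E(a)| / |E(b)| between two networks."""
    if network_a.number_of_edges() == 0 or network_b.number_of_edges() == 0:
        raise ValueError("complexity ratio needs two non-empty networks")
    return network_a.number_of_edges() / network_b.number_of_edges()


def top_k_comorbidities(results: list[PatternResult], k: int = 10,
                        selected_only: bool = True
                        ) -> list[tuple[tuple[str, str], int, float]]:
    """Top-k patterns by frequency: (pair, frequency, odds_ratio).

    Ties broken by odds ratio descending, then by lexicographic pair.
    """
    pool = [r for r in results if r.selected] if selected_only else list(results)
    if len(pool) < k:
        import warnings
        warnings.warn(f"only {len(pool)} patterns available for top-{k}",
                      stacklevel=2)
    ranked = sorted(pool, key=lambda r: (-r.counts.frequency, -r.odds_ratio,
                                         r.counts.pair))
    return [(r.counts.pair, r.counts.frequency, r.odds_ratio)
            for r in ranked[:k]]


def overlap_analysis(top_a, top_b) -> dict[str, list]:
    """Shared and population-specific items of two ranked lists.

    Works for comorbidity pairs and for hub codes alike; items are
    compared by their first element (the canonical key).
    """
    keys_a = {item[0] if isinstance(item, tuple) else item for item in top_a}
    keys_b = {item[0] if isinstance(item, tuple) else item for item in top_b}
    return {
        "shared": sorted(keys_a & keys_b),
        "specific_a": sorted(keys_a - keys_b),
        "specific_b": sorted(keys_b - keys_a),
    }


@dataclass
class ComparisonReport:
    """Full two-population comparison over overall/male/female strata."""

    summaries: dict[str, PopulationSummary]
    hub_reports: dict[str, HubReport]
    complexity_ratios: dict[str, float]  # stratum -> edges(A)/edges(B)
    top_patterns: dict[str, list]
    pattern_overlap: dict[str, dict]
    hub_overlap: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "summaries": {k: s.to_dict() for k, s in self.summaries.items()},
            "networks": {
                k: {"n_nodes": r.complete_network.number_of_nodes(),
                    "n_edges": r.complete_network.number_of_edges(),
                    "hubs": [h for h, _, _ in r.hubs],
                    "unique_pattern_coverage_pct": round2(r.unique_pattern_coverage),
                    "frequency_coverage_pct": round2(r.frequency_coverage),
                    "node_coverage_pct": round2(r.node_coverage)}
                for k, r in self.hub_reports.items()},
            "complexity_ratios": {k: round2(v)
                                  for k, v in self.complexity_ratios.items()},
            "top_patterns": {k: [["+".join(p), f, round2(o)] for p, f, o in v]
                             for k, v in self.top_patterns.items()},
            "pattern_overlap": {
                k: {kk: [list(x) if isinstance(x, tuple) else x for x in vv]
                    for kk, vv in d.items()}
                for k, d in self.pattern_overlap.items()},
            "hub_overlap": self.hub_overlap,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))


def run_full_comparison(cohort_a: Cohort, cohort_b: Cohort, k: int = 10,
                        alpha: float = 0.05, prevalence_floor: float = 1e-4,
                        out_dir: str | Path | None = None) -> ComparisonReport:
    """Run the complete pipeline per population and per sex stratum.

    Builds six networks (overall/male/female for each population), with
    screening, Bonferroni N, and prevalence denominators computed per
    stratum.  Deterministic given inputs and settings; when ``out_dir`` is
    given, writes all pattern tables, node/edge tables, GraphML networks,
    and the machine-readable comparison report.
    """
    strata: dict[str, Cohort] = {}
    for tag, cohort in (("a", cohort_a), ("b", cohort_b)):
        strata[f"{tag}_overall"] = cohort
        by_sex = stratify_by_sex(cohort)
        strata[f"{tag}_male"] = by_sex["male"]
        strata[f"{tag}_female"] = by_sex["female"]

    summaries, hub_reports, top_patterns = {}, {}, {}
    for name, cohort in strata.items():
        summaries[name] = summarize_population(cohort)
        hub_reports[name] = hub_pipeline(cohort, k=k, alpha=alpha,
                                         prevalence_floor=prevalence_floor)
        top_patterns[name] = top_k_comorbidities(hub_reports[name].patterns,
                                                 k=k)
    ratios, pattern_overlap, hub_overlap = {}, {}, {}
    for stratum in ("overall", "male", "female"):
        ra, rb = hub_reports[f"a_{stratum}"], hub_reports[f"b_{stratum}"]
        if (ra.complete_network.number_of_edges()
                and rb.complete_network.number_of_edges()):
            ratios[stratum] = complexity_ratio(ra.complete_network,
                                               rb.complete_network)
        pattern_overlap[stratum] = overlap_analysis(
            top_patterns[f"a_{stratum}"], top_patterns[f"b_{stratum}"])
        hub_overlap[stratum] = overlap_analysis(
            [h for h, _, _ in ra.hubs], [h for h, _, _ in rb.hubs])

    report = ComparisonReport(summaries=summaries, hub_reports=hub_reports,
                              complexity_ratios=ratios,
                              top_patterns=top_patterns,
                              pattern_overlap=pattern_overlap,
                              hub_overlap=hub_overlap)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, hub_report in hub_reports.items():
            patterns_to_frame(hub_report.patterns).to_csv(
                out / f"patterns_{name}.csv", index=False)
            if hub_report.complete_network.number_of_edges():
                node_table(hub_report.complete_network).to_csv(
                    out / f"nodes_{name}.csv", index=False)
                edge_table(hub_report.complete_network).to_csv(
                    out / f"edges_{name}.csv", index=False)
                write_graphml(hub_report.complete_network,
                              out / f"network_{name}.graphml")
            hub_report.to_json(out / f"hubs_{name}.json")
        report.to_json(out / "comparison.json")
    return report
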