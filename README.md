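# mmnet — multimorbidity networks from ICD-10 inpatient records

`mmnet` builds and compares multimorbidity networks from baseline inpatient
hospitalization records coded in ICD-10. It is aimed at epidemiologists and
biostatisticians who want to screen all pairwise comorbidity patterns in a
cohort, assemble the significant ones into a disease network, rank diseases
by network centrality, and compare disease profiles between populations —
and at methodologists who want to validate that pipeline on synthetic
cohorts with known, planted association structure.

## The method

Each patient contributes one **baseline record**: the earliest admission,
reduced to its set of distinct 3-character ICD-10 categories, restricted to
chapters 1–14 (somatic disease) and ages 40–59. For every unordered disease
pair (i, j) co-occurring in at least one record, the patient-level 2×2
table (n11, n10, n01, n00) is tallied and the association estimated by the
unadjusted logistic-regression odds ratio, which for a single binary
covariate is the cross-product ratio

    OR = (n11 · n00) / (n10 · n01),    SE(log OR) = √(1/n11 + 1/n10 + 1/n01 + 1/n00)

with a two-sided Wald p-value (Haldane–Anscombe +0.5 when a cell is empty).
A pattern becomes an edge of the **complete multimorbidity network** iff

1. OR > 1,
2. p < 0.05 / N, where N is the number of patterns with OR > 1 in the same
   cohort or stratum (Bonferroni), and
3. pattern prevalence n11 / n_inpatients > 1/10,000.

On the resulting undirected graph, seven node metrics are computed: degree,
**maximal clique centrality** MCC(v) = Σ_{maximal cliques C ∋ v} (|C|−1)!,
closeness (Wasserman–Faust scaling), local clustering coefficient,
betweenness, PageRank (damping 0.85), and eigenvector centrality
(max-normalized). The ten highest-degree nodes (ties broken by disease
prevalence) are the **hub diseases**; the subnetwork of edges incident to
any hub is the hub-associated network, summarized by its coverage of the
complete network's edges, pattern frequency, and nodes. Two populations are
compared by edge-count complexity ratios, top-k comorbidity overlap, and
hub overlap, per overall/male/female stratum.

The synthetic-cohort generator plants vertex-disjoint disease pairs with a
specified odds ratio ψ: the per-patient joint law is the bivariate
Bernoulli whose cell probabilities solve
(ψ−1)p11² − [1+(p_i+p_j)(ψ−1)]p11 + ψ·p_i·p_j = 0 at the requested
marginals, all other diseases independent — so screening, network, and hub
stages can be validated by parameter recovery.

## Worked example

```python
from mmnet import (SyntheticCohortConfig, generate_cohort, hub_pipeline,
                   summarize_population)
from mmnet.simulate import example_catalog
from mmnet.report import round2

config = SyntheticCohortConfig(
    n_patients=20_000,
    diseases=example_catalog(12, prevalence=0.08),
    planted_pairs=(("A10", "C10", 5.0), ("D10", "E10", 3.0)),
    seed=7,
)
cohort, truth = generate_cohort(config)
summary = summarize_population(cohort)
print(f"multimorbidity: {round2(summary.multimorbidity_pct)}% "
      f"({summary.multimorbidity_count}/{summary.n_inpatients})")
report = hub_pipeline(cohort, k=4)
net = report.complete_network
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges "
      f"(Bonferroni N={report.selection.bonferroni_n})")
for u, v, attrs in net.edges(data=True):
    print(f"edge {u}-{v}: OR={attrs['odds_ratio']:.2f}, "
          f"p={attrs['p_value']:.2e}, frequency={attrs['frequency']}")
```

prints

```
multimorbidity: 24.67% (4933/20000)
network: 4 nodes, 2 edges (Bonferroni N=32)
edge A10-C10: OR=5.40, p=1.58e-151, frequency=424
edge D10-E10: OR=2.87, p=8.08e-50, frequency=288
```

Of the 66 candidate pairs among 12 diseases, exactly the two planted pairs
survive the three selection rules, and their estimated odds ratios (5.40,
2.87) recover the planted ψ = 5 and ψ = 3 within sampling error; the 424
co-occurrences of A10+C10 against an independence expectation of
20,000 × 0.08² = 128 is what the OR measures.

A command-line interface mirrors the library:

```sh
mmnet simulate config.yaml --out cohort.csv
mmnet screen cohort.csv --out patterns.csv
mmnet network cohort.csv --out-dir net/        # GraphML + node/edge CSV
mmnet hubs cohort.csv --out hubs.json
mmnet summarize cohort.csv --out summary.json
mmnet compare cohort_a.csv cohort_b.csv --out-dir cmp/
```

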