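# Methods

## Cohort definition and filtering

The analysis unit is the baseline record: each patient's earliest
admission. When one patient has several admissions on the same earliest
date, their code sets are merged into one record — baseline is treated as
a snapshot of diagnoses, so no same-date row is privileged; age and sex
are taken deterministically from the first row under an (age, sex) sort.
Diagnosis codes are normalized to 3-character ICD-10 categories
(uppercase, dots and subcategory digits stripped) and deduplicated within
a record; all diagnosis positions are treated equally.

Inclusion requires age in [40, 59] (both bounds inclusive) and at least
one code from chapters 1–14. The chapter map is the standard WHO 22-chapter
grouping shipped as a packaged table (`mmnet/data/icd10_chapters.csv`),
with U codes as chapter 22. Lexicographically valid categories that fall
between chapter blocks (D49, E91–E99, V00, ...) map to no chapter and are
removed by the chapter filter like any out-of-scope code. Exclusion counts
per rule are kept on the cohort so selection flowcharts can be rebuilt.

## Association screening

For each co-occurring pair, the 2×2 patient-level table is exact, and the
odds ratio is the cross-product ratio — identical to the exponentiated
slope of an unadjusted logistic regression of one disease's indicator on
the other's, which is why the closed form is used in production and an
actual regression fit (statsmodels GLM) serves only as the independent
oracle in the tests. No age/sex adjustment is applied; strata are instead
screened separately. The default p-value is the two-sided Wald test on the
log odds ratio; `screen_cohort(..., p_method="fisher")` substitutes the
exact (Fisher) p-value. Tables with a zero cell receive the
Haldane–Anscombe correction (+0.5 to all four cells) and are flagged so
the sensitivity of downstream selection can be audited.

Selection applies three strict inequalities: OR > 1; p < 0.05/N with N the
number of OR > 1 patterns in the same cohort or stratum (N is recomputed
per stratum, never shared); and pattern prevalence > 1/10,000 with the
stratum's own inpatient count as denominator. Decreasing alpha or raising
the floor can only remove edges (tested as a monotonicity property).

## Network metrics

All metrics are computed on the unweighted, undirected graph; odds ratio
and frequency are edge attributes only. Maximal cliques come from the
pivoting Bron–Kerbosch enumeration (`networkx.find_cliques`), and

    MCC(v) = Σ over maximal cliques C with |C| ≥ 2, v ∈ C of (|C| − 1)!

in exact integer arithmetic. Singleton cliques are excluded so that the
identity "MCC equals degree whenever v's neighborhood contains no internal
edge" holds for every node, including isolated ones (degree 0 → MCC 0);
counting singletons would put every isolated node at 0! = 1 and break it.

Disconnected graphs use these conventions: closeness with the
Wasserman–Faust component scaling; betweenness on the full graph with raw
(unnormalized) pair counts — so the middle of a 3-node path scores exactly
1, the one pair routed through it (normalization is available via
parameter); PageRank with damping 0.85, tolerance 1e-9, uniform
personalization; eigenvector centrality as the principal eigenvector of
the largest component's adjacency, zero elsewhere, max-normalized. The
eigenvector is obtained by dense symmetric eigendecomposition: the
networks this package targets have at most a few hundred nodes, where
dense `eigh` is both faster and free of the small-component failure modes
of sparse iterative solvers.

## Hubs and comparison

Hubs are the k = 10 (configurable) nodes ranked by degree descending,
ties broken by disease prevalence descending, residual ties by code order.
Coverage percentages divide the hub-associated subnetwork's edge count,
total pattern frequency, and node count by the complete network's, per
stratum. Complexity between populations is the edge-count ratio. Top-k
comorbidity lists rank selected patterns by frequency, ties by odds ratio
then pair order. Percentages and ratios are printed to two decimals with
half-up rounding.

Per-capita diagnoses count distinct 3-character codes per baseline record
(deduplicated) — the same definition pattern enumeration uses — divided by
inpatient count, optionally stratified by single year of age and chapter;
the chapter breakdown sums exactly to the overall per-capita at each age.

## Synthetic cohorts

The generator emulates the structure of baseline inpatient cohorts:
n patients with uniform integer ages over [40, 59], sex by a configured
fraction, and per-patient sets of in-scope ICD-10 categories. Marginal
prevalences are exact Bernoulli parameters. Association is planted only on
vertex-disjoint pairs: for a pair with odds ratio ψ the joint cell
probabilities are the Plackett (bivariate Bernoulli) solution

    (ψ−1)·p11² − S·p11 + ψ·p_i·p_j = 0,   S = 1 + (p_i + p_j)(ψ−1),

taking the admissible root inside the Fréchet bounds (for ψ = 1, p11 =
p_i·p_j); all remaining diseases are independent. Every patient is kept,
including the patients who draw no disease, so prevalence and odds-ratio
denominators match the configured law exactly — unlike a real filtered
cohort, where code-free records cannot occur. The single seeded stream has
fixed order (sex, age, planted pairs in config order, remaining diseases
in catalog order), making generation a pure function of the config.

What the generator does **not** emulate: realistic marginal prevalence
profiles, chapter-specific frequency patterns, higher-order dependence
(every planted structure is pairwise and vertex-disjoint), age- or
sex-dependent disease risk, and longitudinal admission histories. Passing
recovery tests therefore demonstrate correctness of the estimation and
selection machinery under the stated joint law, not robustness to
confounding or dependence structures real populations exhibit.

## Validation problem sizes

Parameter recovery uses 50 cohorts of n = 20,000 patients with 20
diseases at prevalence 0.05 and one planted pair at ψ = 5; family-wise
error control uses 200 null cohorts of n = 10,000 with 20 independent
diseases at prevalence 0.1; oracle equivalence uses 200 random
all-positive 2×2 tables and 100 random graphs of up to 12 nodes against
exhaustive enumeration. These sizes give each check stable statistics
while keeping the whole suite inside a few minutes on one CPU.

## Known limitations

* **Wald p-values at Bonferroni thresholds.** With ~190 candidate pairs,
  the adjusted threshold sits near 5×10⁻⁴ (|z| ≈ 3.5), deep in the tail
  where the normal approximation to the log odds ratio on discrete 2×2
  tables is mildly anti-conservative. On null cohorts the family-wise
  probability of selecting at least one edge therefore runs modestly above
  the nominal 5% (the null-cohort simulation in the acceptance suite
  measures this directly). The Bonferroni guarantee is exact only for
  valid p-values; `p_method="fisher"` restores it, at the price of
  conservatism, and the corresponding unit test verifies the controlled
  rate. The Wald default is retained because the screening method is
  defined by logistic-regression p-values.
* Associations are unadjusted; strata are the only confounder control.
* Planted truth is only exact for vertex-disjoint pairs; no multivariate
  dependence model is provided.
* The hub definition is degree-based; MCC- or PageRank-ranked hub lists
  can be derived from the exported metric tables but are not a pipeline
  default.
* No temporal ordering of diseases: networks are undirected snapshots of
  baseline co-occurrence.
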