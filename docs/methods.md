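# Methods

## Problem and data model

The package asks whether two families of quantities used in drug-combination
discovery carry information about clinical drug–drug interaction (DDI)
severity: (i) cell-line synergy scores (Bliss, HSA, Loewe, ZIP and the S
variants S_max/S_mean/S_sum), consumed at the summary level as one value per
(drug A, drug B, cell line) row, and (ii) pairwise "toxicity-penalty" metrics
— target-set and pathway-set Jaccard overlap, Morgan-fingerprint Tanimoto
similarity, average shortest-path distance between target sets on a
protein–protein interaction network (PPIN), and the Jaccard overlap of
two-hop target neighborhoods.

Severity is a three-level ordinal variable, Minor (0) < Moderate (1) <
Major (2), attached to the unordered drug pair. DrugBank-style sources encode
it numerically (0/1/2), DDInter-style sources as words; other DDInter
categories (e.g. "Unknown") are dropped with a logged count. The unit of
observation is the (pair, cell line) row: per-pair metrics are computed once
and broadcast to a pair's rows, because none of them depend on cell line.

Joins across sources use normalized drug names (lowercase, whitespace and
punctuation stripped; idempotent) with an optional user-supplied synonym
table; no fuzzy matching is attempted, because fuzzy matches cannot be
audited. Conflicting severity entries for the same pair within one source
keep the maximum severity — the clinically precautionary choice — with the
conflict count logged; a `first` policy is available. Protein accessions are
opaque strings except that isoform suffixes ("-n") are stripped by default
(configurable). An observation is retained when it has at least one synergy
score and at least one source's severity label; per-source analyses subset
later. All filters log before/after counts into the dataset provenance.

## Pair metrics

- **Jaccard** |A∩B|/|A∪B| with the empty-empty convention 0. A drug with *no
  recorded targets at all* yields an absent (NaN) metric instead — "no data"
  is deliberately distinguished from "no demonstrated overlap".
- **Pathway sets** are unions over a drug's targets of each protein's pathway
  memberships, under two views of the hierarchy: leaf-level only ("lowest")
  and all levels. The union-over-targets construction (rather than
  per-target averaging) matches the set-per-drug flow of the analysis; the
  all view is maintained as a superset of the lowest view, repairing
  violations by union with a warning.
- **Morgan fingerprints** are 2048-bit hashed circular-substructure vectors,
  radius 2 (the conventional ECFP4-like default; the bit length is fixed by
  the study design, the radius exposed in config), generated with RDKit.
  Unparseable SMILES mark the drug's structural similarity absent with a
  warning rather than failing the run. Tanimoto on bit vectors is
  algebraically identical to Jaccard on on-bit sets; the test suite asserts
  exact equality.
- **Network metrics** treat the PPIN as an undirected simple graph with unit
  edge weights, so Dijkstra distances reduce to breadth-first distances and
  are computed as such. Unreachable or unmappable target pairs are *excluded*
  from the average-distance mean by default (an imputation constant would
  dominate the mean; an `impute:<value>` policy is available and exclusion
  counts are logged). Two-hop neighborhoods include the seed targets
  themselves; k = 0 gives exactly the mapped targets.

## Statistical battery

Applied to every (variable × severity-source) cell, always in full — the
normality screen justifies the nonparametric choice but never switches the
pipeline to parametric tests:

- **D'Agostino–Pearson** K² omnibus normality test (scipy's implementation;
  requires n ≥ 20).
- **Kruskal–Wallis** with midranks and the standard tie correction. The
  effect size is **η² = H/(N−1)**, the proportion of rank variance explained
  by group membership; this plain variant (not (H−k+1)/(N−k)) is the
  package's primary definition because sample sizes differ strongly between
  severity sources and the plain form divides by the same quantity the rank
  variance is computed over.
- **Dunn's test** on mean ranks with the pooled tie correction; two-sided
  p-values are Bonferroni-multiplied by the number of contrasts (3 for three
  severity levels) and capped at 1. Each contrast also carries **Cliff's δ**
  (P(x>y) − P(x<y), computed by sorted-rank counting). For k = 2 Dunn's z
  coincides with the tie-corrected asymptotic rank-sum z, which the tests
  exploit as an independent scipy cross-check.
- **Jonckheere–Terpstra** for an a-priori ordered location trend:
  J = Σ_{i<j} [#{x<y} + ½#{x=y}] over ordered group pairs. The normal
  approximation uses the tie-corrected null mean and variance and a 0.5
  continuity correction on the tail probability: J is discrete, and without
  the correction the approximate one-sided p drifts from the exact
  permutation p by up to ~0.03 at group sizes ≤ 8, versus < 0.01 with it.
  The permutation mode — exhaustive enumeration when the number of distinct
  assignments fits the budget, Monte-Carlo otherwise — is the arbiter
  wherever the two disagree. Both one-sided directions are reported for every
  variable. The effect size is **r = Z/√N** from the uncorrected Z; |r| ≤ 1
  and reads like a correlation coefficient. (The square-root scaling is the
  only reading under which that bound holds.)
- **Correlation suite**: Pearson r, Spearman ρ, and the OLS best-fit line
  with R² = r², for synergy-vs-overlap scatter reconstruction.

Cells failing preconditions (any severity class below `n_min`, default 20, or
zero variance) are emitted as explicit rows with a reason code so the
variable × source grid is always complete. No multiple-testing correction is
applied across metrics or sources; Bonferroni acts only inside each post-hoc
family of three contrasts.

## Synthetic data generator

The generator emulates the joint structure the analysis assumes, not
pharmacology: drugs draw SMILES from a fixed palette of 50 valid drug-like
molecules (random SMILES strings are rarely parseable; a `fingerprint_only`
mode emits random bit vectors and skips chemistry for fast tests); each drug
draws 1–5 targets from a synthetic proteome (300 proteins by default); the
PPIN is a Barabási–Albert preferential-attachment graph (m = 3; a
random-geometric alternative is available) with STRING-style node IDs and a
UniProt-style ID map; pathways form a complete b-ary tree (depth 4,
branching 3) with each protein in exactly one leaf, giving lowest-view size 1
and all-view size = depth per protein; each pair receives 1–3 synthetic cell
lines to exercise the triplicate-row unit.

Severity marginals default to (0.10, 0.31, 0.59) — a Major-heavy mix typical
of curated DDI severity tables. Two couplings can be planted:

- **synergy ← toxicity**: each score is z·τ + ε with z the standardized
  ordinal severity, τ = `synergy_toxicity_trend` and ε ~ N(0, noise_sd);
  defaults τ = 0 (no trend) and noise_sd = 1.
- **toxicity ← metric**: a Gaussian copula on the metric's ranks redraws the
  severity labels to correlate with a chosen pair metric at the requested
  strength while preserving the marginals in expectation. Rank coupling makes
  the planted strength invariant to the metric's marginal distribution —
  though heavy ties (e.g. a mostly-zero sparse target Jaccard) attenuate it,
  which is why calibration fixtures couple against continuous metrics.

A `db_disagreement` fraction re-draws the DDInter-dialect labels to emulate
severity disagreement between curated sources. Everything is driven by one
integer seed through spawned child generators; identical config + seed gives
byte-identical output files (all iteration is over sorted containers).

What the generator does **not** emulate: dose–response surfaces underlying
the synergy summaries, realistic target-degree or pathway-size distributions,
name ambiguity across sources, and the strong drug-sharing dependence of real
pair panels. Passing tests therefore demonstrate that the pipeline recovers
couplings of known strength and direction under clean sampling assumptions —
not that any particular real-data result is correct. One such dependence
effect is visible even synthetically: when many pairs share drugs and pairs
repeat across cell lines, observations are clustered and null trend-test
p-values become anti-conservative; the selectivity fixtures therefore use one
cell line per pair and a large drug pool.

## Validation study sizes

The packaged validation (test suite and `scripts/acceptance.py`) uses: 200
random fixtures for exact oracle agreement (sets ≤ 30 elements, graphs ≤ 50
nodes via Floyd–Warshall, fingerprints 64–2048 bits); 10,000 null simulations
(3 groups × 30) for type-I calibration of KW/Dunn/JT against the 4–6% band;
100 small all-distinct datasets for permutation-vs-approximation agreement
within 0.02; 200 seeds × 4 coupling strengths {0, 0.1, 0.3, 0.5} at 3,000
pairs for trend power (≥ 99% at 0.5, ~5% at 0) and strict monotonicity of the
mean recovered r; 800 pairs on a 200-protein network for the directional
sign-flip scenario; 10,000 pairs for the independence study (all |r| < 0.05,
R² < 0.0025); and a 250-pair full-stack double run for byte determinism.

## Known limitations

- Trend tests assume independent observations; with triplicate rows and
  shared drugs the reported p-values are optimistic (this mirrors the
  row-level design of the analyses the pipeline reproduces; the
  `--collapse-pairs`-style aggregation of scores per pair is the available
  sensitivity check).
- The Jonckheere–Terpstra permutation mode is exact only when the assignment
  count fits `n_perm`; otherwise Monte-Carlo error of order (p(1−p)/n_perm)^½
  applies.
- Severity is treated as exchangeable across sources only up to the label
  scale; no attempt is made to reconcile *why* sources disagree.
- The average-distance exclusion policy changes the estimand when networks
  are fragmented; the logged exclusion counts should be inspected before
  comparing values across networks.
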