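# Methods

This note documents the models, conventions and numerical choices behind
`pinlineage`, in the order the pipeline applies them, plus the design of
the synthetic-data generator and what passing tests do and do not show.

## Expression calls

A gene's stage-level expression is the mean of its values over that
stage's samples carrying a present ('P') detection call. The gene is
expressed when it has at least one present sample **and** the mean
strictly exceeds the threshold (default 200 expression units on the
linear MAS5-like scale; 150 and 250 are the conventional sensitivity
alternates). Conventions worth stating:

* Marginal ('M') calls count as not-present. Only "present" has a
  defined role in the averaging rule; treating 'M' as present would
  silently admit unreliable probes.
* A gene with no present sample is unexpressed regardless of its values
  — the present-only mean is undefined there, and the call mask is the
  more trustworthy signal.
* The threshold comparison is strict ('>'): a mean of exactly 200 is
  not expressed.
* Multi-probe genes keep the probe with the highest variance across
  *all* samples of the dataset (not per stage), so one probe choice
  holds for every stage and stage sets stay comparable. Exact variance
  ties go to the lexicographically smaller probe id for determinism.

Cross-condition comparison of raw expression values is deliberately
absent: the two conditions may come from different protocols, and the
pipeline only ever compares binarized (expressed / unexpressed) states.

## Expressed PINs and turnover

The expressed PIN of a stage keeps every reference interaction whose two
endpoints are both expressed. Expressed proteins without an expressed
partner are counted as expressed but excluded from the graph. Appearing
and disappearing edge sets are plain set differences between consecutive
stages. The pooled series ratios normalize appearing edges by the later
stage's edge count and disappearing edges by the earlier stage's, summed
over transitions — each ratio is then a fraction in [0, 1] with a direct
reading ("fraction of this stage's interactions that are new / lost").
Pooling, rather than averaging per-transition ratios, weights each
transition by its size; with near-constant stage sizes the two agree to
rounding.

The null model shuffles "expressed" labels over the interaction
universe: per stage, a uniform random subset with exactly the observed
edge count, independent across stages and replicates (default 1,000).
Two alternatives are deliberately not offered. Shuffling *protein*
labels deflates the expected edge count on degree-heterogeneous
networks (low-degree proteins dominate the draw), and degree-preserving
rewiring invents edges outside the universe; both would bias the
expected turnover downward. Significance is
z = (r_obs − mean(r_null)) / sd(r_null) with the sample (n−1) standard
deviation; an all-equal null raises an explicit degenerate-null error
rather than returning ±inf.

Under independent uniform subsets of sizes m from a universe of N, the
expected appearing (and disappearing) ratio is 1 − m/N; the acceptance
script checks the sampler against this closed form.

## Map-equation module detection

The two-level map equation for an undirected, unweighted graph scores a
partition M by the expected per-step code length of a random walk,

    L(M) = q H(Q) + Σ_i p_i⟲ H(P_i)   [bits]

with node visit rates p_α = k_α / 2m (degree-proportional, no
teleportation — PINs are undirected, and teleportation would add an
arbitrary parameter), module exit rates q_i = cut_i / 2m, and the
equivalent collapsed form
L = f(q) − 2Σf(q_i) + Σf(q_i + s_i) − Σf(p_α), f(x) = x log₂ x, used
internally because only its first three terms depend on the partition.

The required optimizer is self-contained: Louvain-style sweeps of
single-node moves scored by exact O(deg) map-equation deltas, module
aggregation, recursion on the aggregated graph, and a final node-level
refinement pass — restarted `trials` times (default 100; 1,000 is the
full-fidelity convention) from seeded random orders, keeping the
minimum-L partition with canonical-form tie-breaking so output is a
pure function of the seed. On random connected graphs of ≤ 7 nodes the
optimizer attains the exhaustive-enumeration optimum (Bell-number
search, `brute_force_partition`); this is an acceptance check.
`python-igraph`'s compiled Infomap and Louvain are pluggable backends;
their candidate partitions are still selected by this package's own
map-equation value, keeping the objective single-sourced.

Modules with fewer than 3 proteins are filtered out and their members
reported as unassigned; they take no part in tracking, correspondence
or enrichment.

## Lineage tracking

C_N, C_L and C_GO are Jaccard indices over module protein sets, induced
edge sets and GO BP term unions. Conventions:

* The C_GO feature set is the union of members' BP terms (not
  enriched-only terms): it needs no significance machinery and is
  monotone under membership change. When both term sets are empty,
  C_GO = 1 — the annotation state did not change, so inheritance is
  decided by C_L alone; empty-vs-nonempty gives 0.
* Pairing is mutual-best by C_L with deterministic tie-breaking
  (higher C_N, then higher C_GO, then smallest member symbol).
* Inheritance thresholds are strict ('exceeds 0.5'), configurable over
  the conventional 0.3–0.7 sensitivity range; raising them can only
  remove inherited links (a tested monotonicity).
* Every module belongs to exactly one maximal chain. Status by span
  over T stages: 1..T inherited; anchored at stage 1 but broken early
  disrupted; late start surviving to T appearing; late start broken
  early disappearing. The last case is the package's own convention —
  endpoint-anchored definitions leave middle chains ambiguous, and a
  chain that both appears and vanishes is counted with the vanishing
  ones since that is its terminal event.

## Disease-disruption typing

Conditions are aligned positionally (equal stage counts required).
Correspondence at an aligned stage uses the same mutual-best C_L
machinery across conditions, flags strict as above, each stage evaluated
independently (no chaining across conditions). For an inherited aging
lineage with flags b1..bT: late-disrupted iff b1 ∧ ¬bT; early-disrupted
iff ¬b1 ∧ (b2 ∨ … ∨ bT); everything else — including gap patterns like
(T,F,T,T) — is "other", because only the endpoint-anchored types have a
defined biological reading (collapse late in disease vs. absent early).

## Enrichment

Interactions inherit the BP terms *common to both endpoints*; an empty
intersection leaves the interaction unannotated and outside the
background N (N counts annotated interactions only). Significance is the
standard upper-tail hypergeometric P(X ≥ x) — the conventional overlap
statistic — computed via `scipy.stats.hypergeom.sf` and verified against
exact integer-arithmetic subset counting for all N ≤ 25. FER =
(x/m)/(n/N). Assignment requires p < 0.05 and FER > 2, both strict, on
raw p-values; Benjamini–Hochberg is available behind a flag but off by
default to match the raw-p convention. Manual GO curation is not
reproducible mechanically; an optional term-collapse map (fine term →
umbrella term) substitutes for it and defaults to identity.

## Exact Wilcoxon comparison

Per-stage counts (4 per condition in the canonical design) are compared
by complete enumeration of all C(n1+n2, n1) rank assignments with
midranks for ties; two-sided p = 2·min(tail probabilities) capped at 1.
For fully separated groups of four this gives 2/70 ≈ 0.0286. Outside
group sizes 2–10 the normal approximation is used with a logged warning.

## Synthetic-data generator

The generator's defaults define the study conditions used by the
end-to-end tests and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| n_proteins / background edges | 800 / ~2400 | desk-scale network dense enough for ~70 modules per stage |
| background topology | preferential attachment (m = 3) | matches the degree heterogeneity that motivates the label-shuffle null |
| planted modules | 25 × 12 proteins, intra-edge prob 0.8 | dense enough that detection and C_L > 0.5 tracking are well-posed, sparse background keeps them distinct |
| stages × samples | 4 × 4 | the canonical four ordered stage groups, four arrays each |
| baseline expressed fraction | 0.8 | brain-like expressed fraction (~70–90% of genes) |
| stable turnover | 0.02 / stage | small background churn; no quantitative estimate exists for normal aging, so this is a free parameter chosen once |
| disrupted modules / schedule | 5 modules, (0, 0, 0.6, 1.0) | "late-silenced": intact early, fully silenced at the final stage |
| expression means (high/low) | 1000 / 30 | well clear of the 200 threshold on both sides |
| noise | lognormal, linear-scale sd 100 | <2% binarization error; zero noise reproduces the truth exactly |
| GO | 150 background terms (3/protein) + 3 dedicated terms per planted module | coherent within-module function over random background |

Planted modules are always expressed in the stable condition, so they
survive as fully expressed subgraphs at every stage; background proteins
follow a stationary two-state Markov chain whose symmetric-difference
turnover is ~2%/stage of the expressed set. The disease condition draws
its background churn independently from the same law (an all-zero
disruption schedule is therefore a true null), and silences disrupted
modules cumulatively in a per-module random member order
(⌊schedule[t]·size⌋ members off at stage t). The schedule is *not*
required to be monotone: an early-silenced, later-restored schedule
(e.g. (1, 0, 0, 0)) is the designed probe for early-disruption calls;
the non-increasing-expression invariant applies only to monotone
schedules. Present calls are (truly expressed ∧ value above the
high/low midpoint), so the call mask carries information independent of
the 200 threshold, as in real detection calls.

What the generator does **not** emulate: probe-level data and MAS 5.0
internals (the pipeline consumes their outputs), batch effects between
conditions (the analysis is binarized precisely to avoid cross-condition
value comparison), overlapping modules, and annotation incompleteness
structured by study bias. Passing end-to-end tests therefore shows the
machinery recovers planted structure under controlled noise — not that
real-data results at published scale are reproduced.

## Problem sizes and determinism

End-to-end runs in the test suite and the acceptance script use the
default generator scale with 30 optimizer trials per PIN and 120–500
null replicates; single-graph oracle checks use 100 trials; the
full-fidelity conventions (1,000 trials, 1,000 replicates) are plain
configuration away. Every stochastic component — generator, optimizer
restarts, null sampler — draws from `numpy` Generators seeded from a
single integer, and graph construction orders are canonicalized
(sorted) so results are identical across processes regardless of hash
randomization.

## Known limitations

* Identifier joins are by official gene symbol; no probe-to-symbol or
  cross-database mapping beyond the explicit probe-map input.
* The internal optimizer is two-level only (no hierarchical map
  equation) and targets desk-scale PINs (10³–10⁴ edges); paper-scale
  networks are better served by the igraph Infomap backend.
* Lineage tracking is one-to-one (mutual best); module merges and
  splits are not modelled.
* Classification of gap-containing correspondence vectors is
  deliberately conservative ("other").
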