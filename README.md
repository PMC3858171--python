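# pinlineage

Temporal analysis of protein-interaction networks (PINs) across ordered
disease or aging stages. `pinlineage` is aimed at systems biologists who
have (a) a reference protein-interaction table, (b) stage-labelled
expression profiles with Affymetrix-style detection calls, and (c) GO
biological-process annotations, and who want to know **which network
modules stay intact across stages and which collapse under disease**.

## What it computes

1. **Expressed PINs.** A gene counts as expressed in a stage when the
   mean of its values over present-called ('P') samples strictly exceeds
   a threshold (default 200 on the linear MAS5-like scale; multi-probe
   genes are collapsed to the highest-variance probe). The stage's
   expressed PIN is the subgraph of the reference network whose edges
   have both endpoints expressed.
2. **Interaction turnover vs. a shuffle null.** Between consecutive
   stages, appearing edges are E(t+1)\E(t) and disappearing edges are
   E(t)\E(t+1); pooled ratios are compared against an edge-label-shuffle
   null (uniform same-size subsets of the interaction universe, default
   1,000 replicates) through z = (r_obs − r̄_null)/σ_null.
3. **Map-equation modules.** Each PIN is partitioned by minimizing the
   two-level map equation
   `L(M) = q H(Q) + Σᵢ pᵢ H(Pᵢ)` (bits, degree-proportional visit
   rates, no teleportation) with a self-contained multi-start greedy
   optimizer (igraph's Infomap/Louvain are optional backends). Modules
   with fewer than 3 proteins are discarded.
4. **Module lineages.** Consecutive-stage module pairs are scored by the
   Jaccard auto-correlations of proteins (C_N), interactions (C_L) and
   GO BP terms (C_GO); mutual-best pairs with C_L > 0.5 and C_GO > 0.5
   are "inherited", and maximal chains of inherited links form lineages
   (inherited / appearing / disappearing / disrupted by span).
5. **Disease-disrupted modules.** The two conditions are aligned
   stage-by-stage; each inherited aging lineage gets a per-stage
   cross-condition correspondence flag and is typed **late-disrupted**
   (corresponds early, not at the end), **early-disrupted** (no early
   correspondence, recovers later) or **other**.
6. **Module function.** Each interaction inherits the GO BP terms shared
   by both endpoints; per (module, term), significance is the upper-tail
   hypergeometric probability of the overlap x out of m module
   interactions against n of N annotated interactions, with fold
   enrichment FER = (x/m)/(n/N); a term is assigned when p < 0.05 and
   FER > 2.
7. **Condition comparison.** Per-stage counts are compared between
   conditions with an exact two-sided Wilcoxon rank-sum test (complete
   enumeration, midranks for ties).

A ground-truthed synthetic-data generator (`pinlineage.synthetic_data`)
emulates the full data shape — preferential-attachment background
network, planted dense modules, stage-wise expression with detection
calls, module-coherent GO annotations, and a disease condition that
progressively silences chosen modules — so the entire pipeline is
testable without any downloads.

## Worked example

```sh
$ pinlineage synth --out demo --seed 4 --n-proteins 300 --n-modules 10
fixture written to demo
$ pinlineage run --config demo/config.yaml
stable: 35 lineages, inherited ratio 0.5143
disease: 56 lineages, inherited ratio 0.2143
disruption calls: 2 early, 5 late, 11 other
results written to demo/results
```

The fixture plants 10 dense modules, 5 of which are silenced late in the
disease condition. The run recovers the expected picture: the stable
condition keeps half of its module lineages inherited end-to-end, the
disease condition keeps far fewer (0.21 vs 0.51), and exactly the 5
late-silenced modules surface as late-disrupted calls. Full per-module,
per-lineage, per-term tables are written under `demo/results/`
(`modules.tsv`, `lineages.tsv`, `disruption_calls.tsv`,
`delta_ratios.tsv`, `enrichment.tsv`, `expressed_counts.tsv`).

The exact Wilcoxon test is also available standalone; for two fully
separated groups of four it gives the classic 2/70:

```sh
$ pinlineage compare-conditions a.txt b.txt
P-value = 0.02857
```

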