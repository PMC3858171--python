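"""Ground-truthed synthetic data for the whole pipeline.

The generator emulates the data shape the analysis consumes: a
degree-heterogeneous (preferential-attachment) background interaction
network with dense planted modules overlaid; four ordered stages per
condition; per-stage truly-expressed protein sets in which planted
modules are fully expressed at every stable-condition stage while
background proteins churn at a small per-stage turnover rate; a disease
condition in which designated modules are progressively silenced
according to a per-stage schedule; expression values drawn log-normally
around a high (above the 200 detection threshold) or low mean with
Affymetrix-style present/absent calls; and GO annotations in which each
planted module's members share dedicated terms on top of random
background terms.

Everything is a deterministic function of the config's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io_formats import ExpressionDataset, InteractionSet, canonical_edge

CONDITIONS = ("stable", "disease")


@dataclass(frozen=True)
class GeneratorConfig:
    n_proteins: int = 800
    n_interactions: int = 2400
    n_planted_modules: int = 25
    planted_sizes: tuple[int, ...] | None = None  # default: 12 each
    intra_module_edge_prob: float = 0.8
    n_stages: int = 4
    samples_per_stage: int = 4
    baseline_expressed_fraction: float = 0.8
    turnover_rate_stable: float = 0.02
    disrupted_module_ids: tuple[int, ...] = (0, 1, 2, 3, 4)
    disruption_schedule: tuple[float, ...] = (0.0, 0.0, 0.6, 1.0)
    expression_high_mean: float = 1000.0
    expression_low_mean: float = 30.0
    noise_sd: float = 100.0
    n_go_terms_background: int = 150
    terms_per_module: int = 3
    seed: int = 0

    def sizes(self) -> tuple[int, ...]:
        if self.planted_sizes is not None:
            return tuple(self.planted_sizes)
        return tuple([12] * self.n_planted_modules)

    def validate(self) -> None:
        sizes = self.sizes()
        if len(sizes) != self.n_planted_modules:
            raise ConfigurationError(
                f"{self.n_planted_modules} planted modules but "
                f"{len(sizes)} planted sizes"
            )
        if any(s < 5 for s in sizes):
            raise ConfigurationError("planted module sizes must each be >= 5")
        if sum(sizes) > self.n_proteins:
            raise ConfigurationError("planted modules do not fit in n_proteins")
        for name in ("intra_module_edge_prob", "baseline_expressed_fraction",
                     "turnover_rate_stable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if len(self.disruption_schedule) != self.n_stages:
            raise ConfigurationError("disruption_schedule needs one entry per stage")
        if any(not 0.0 <= f <= 1.0 for f in self.disruption_schedule):
            raise ConfigurationError("disruption_schedule fractions outside [0, 1]")
        if any(
            i < 0 or i >= self.n_planted_modules for i in self.disrupted_module_ids
        ):
            raise ConfigurationError("disrupted_module_ids outside planted range")
        if self.n_stages < 2 or self.samples_per_stage < 1:
            raise ConfigurationError("need >= 2 stages and >= 1 sample per stage")
        if not self.expression_low_mean < 200.0 < self.expression_high_mean:
            raise ConfigurationError(
                "expression means must straddle the 200-unit detection threshold"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    config: GeneratorConfig
    proteins: tuple[str, ...]
    interactions: InteractionSet
    planted_modules: tuple[frozenset[str], ...]
    module_of: dict[str, int]  # absent key = background protein
    expressed: dict[str, tuple[frozenset[str], ...]]  # condition -> per stage
    annotations: dict[str, frozenset[str]]
    module_terms: tuple[frozenset[str], ...]


def _protein_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _background_edges(names, n_edges, rng) -> set[tuple[str, str]]:
    """Preferential-attachment-style graph with ~n_edges edges."""
    n = len(names)
    m = max(1, round(n_edges / max(n - 1, 1)))
    import networkx as nx

    g = nx.barabasi_albert_graph(n, m, seed=np.random.RandomState(rng.integers(2**31)))
    return {canonical_edge(names[a], names[b]) for a, b in g.edges}


def generate_truth(config: GeneratorConfig) -> GroundTruth:
    """Generate the ground-truth network, expression schedule and annotations.

    The disease condition's background churn follows the same generative
    law as the stable condition (so an all-zero disruption schedule is a
    true null); disrupted-module members are silenced cumulatively in a
    per-module random order, the member count silenced at stage t being
    ``floor(schedule[t] * size)``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    names = _protein_names(config.n_proteins)

    edges = _background_edges(names, config.n_interactions, rng)
    sizes = config.sizes()
    member_pool = rng.permutation(config.n_proteins)
    planted: list[frozenset[str]] = []
    module_of: dict[str, int] = {}
    pos = 0
    for j, size in enumerate(sizes):
        members = sorted(names[i] for i in member_pool[pos : pos + size])
        pos += size
        planted.append(frozenset(members))
        for p in members:
            module_of[p] = j
        for a_i in range(size):
            for b_i in range(a_i + 1, size):
                if rng.random() < config.intra_module_edge_prob:
                    edges.add(canonical_edge(members[a_i], members[b_i]))
    interactions = InteractionSet(frozenset(edges), source="synthetic")

    planted_members = frozenset().union(*planted) if planted else frozenset()
    background = [p for p in names if p not in planted_members]
    f = config.baseline_expressed_fraction
    tau = config.turnover_rate_stable

    def churn_series(stream) -> list[set[str]]:
        state = {p: stream.random() < f for p in background}
        out = [set(p for p, on in state.items() if on)]
        p_off = tau / 2.0
        p_on = min(1.0, (tau / 2.0) * f / (1.0 - f)) if f < 1.0 else 0.0
        for _ in range(1, config.n_stages):
            for p, on in state.items():
                if on:
                    if stream.random() < p_off:
                        state[p] = False
                elif stream.random() < p_on:
                    state[p] = True
            out.append(set(p for p, on in state.items() if on))
        return out

    stable_bg = churn_series(np.random.default_rng([config.seed, 202]))
    disease_bg = churn_series(np.random.default_rng([config.seed, 303]))

    silence_order = {
        j: [sorted(planted[j])[i] for i in
            np.random.default_rng([config.seed, 404, j]).permutation(len(planted[j]))]
        for j in config.disrupted_module_ids
    }

    expressed: dict[str, tuple[frozenset[str], ...]] = {}
    for cond, bg_series in (("stable", stable_bg), ("disease", disease_bg)):
        stages = []
        for t in range(config.n_stages):
            genes = set(bg_series[t]) | set(planted_members)
            if cond == "disease":
                for j in config.disrupted_module_ids:
                    k = math.floor(config.disruption_schedule[t] * len(planted[j]))
                    genes -= set(silence_order[j][:k])
            stages.append(frozenset(genes))
        expressed[cond] = tuple(stages)

    ann_rng = np.random.default_rng([config.seed, 505])
    bg_terms = [f"BG{i:04d}" for i in range(1, config.n_go_terms_background + 1)]
    module_terms = tuple(
        frozenset(f"MT{j:03d}_{k}" for k in range(1, config.terms_per_module + 1))
        for j in range(config.n_planted_modules)
    )
    annotations: dict[str, frozenset[str]] = {}
    for p in names:
        terms = set(
            bg_terms[i] for i in ann_rng.choice(len(bg_terms), size=3, replace=False)
        )
        j = module_of.get(p)
        if j is not None:
            terms |= module_terms[j]
        annotations[p] = frozenset(terms)

    return GroundTruth(
        config=config,
        proteins=tuple(names),
        interactions=interactions,
        planted_modules=tuple(planted),
        module_of=module_of,
        expressed=expressed,
        annotations=annotations,
        module_terms=module_terms,
    )


def generate_stage_series(truth: GroundTruth, condition: str) -> ExpressionDataset:
    """Expression values plus P/A calls for one condition, all stages.

    Truly-expressed genes are drawn log-normally around the high mean and
    unexpressed genes around the low mean (multiplicative noise scaled so
    the linear-scale sd is ``noise_sd``; zero noise yields the mean
    exactly).  A sample is called present when the gene is truly
    expressed *and* its value clears the midpoint between the two means,
    so the call mask is informative independently of the 200 threshold.
    """
    if condition not in CONDITIONS:
        raise InputError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 707, CONDITIONS.index(condition)])
    n_genes = len(truth.proteins)
    stages = [str(t + 1) for t in range(cfg.n_stages)]
    columns = [
        f"{condition}_s{t + 1}_r{r + 1}"
        for t in range(cfg.n_stages)
        for r in range(cfg.samples_per_stage)
    ]
    midpoint = (cfg.expression_high_mean + cfg.expression_low_mean) / 2.0
    values = np.empty((n_genes, len(columns)))
    calls = np.empty((n_genes, len(columns)), dtype=object)
    gene_index = {g: i for i, g in enumerate(truth.proteins)}
    col = 0
    for t in range(cfg.n_stages):
        on = truth.expressed[condition][t]
        means = np.where(
            [g in on for g in truth.proteins],
            cfg.expression_high_mean,
            cfg.expression_low_mean,
        )
        for _r in range(cfg.samples_per_stage):
            if cfg.noise_sd == 0.0:
                v = means.astype(float)
            else:
                cv2 = (cfg.noise_sd / means) ** 2
                sigma = np.sqrt(np.log1p(cv2))
                z = rng.standard_normal(n_genes)
                v = means * np.exp(sigma * z - sigma**2 / 2.0)
            values[:, col] = v
            expressed_mask = means == cfg.expression_high_mean
            calls[:, col] = np.where(expressed_mask & (v > midpoint), "P", "A")
            col += 1
    sample_stages = {
        c: c.split("_s")[1].split("_")[0] for c in columns
    }
    values_df = pd.DataFrame(values, index=list(truth.proteins), columns=columns)
    calls_df = pd.DataFrame(calls, index=list(truth.proteins), columns=columns)
    return ExpressionDataset(values_df, calls_df, sample_stages)


def write_fixture(truth: GroundTruth, datasets: dict[str, ExpressionDataset], directory) -> list[Path]:
    """Write the fixture file set readable by :mod:`pinlineage.io_formats`.

    Files: ``interactions.tsv`` (2-column edge list),
    ``expr_<condition>_<stage>.tsv`` / ``calls_<condition>_<stage>.tsv``
    per stage, ``samples.tsv``, ``annotations.tsv`` (two-column dialect)
    and ``truth.tsv`` (protein, planted module id or -1, per-condition
    per-stage truly-expressed flags).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = directory / "interactions.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("#symbol_a\tsymbol_b\n")
        for a, b in sorted(truth.interactions.pairs):
            fh.write(f"{a}\t{b}\n")
    written.append(p)

    sample_rows = []
    for cond, ds in datasets.items():
        for stage in ds.stages:
            cols = ds.stage_samples(stage)
            pe = directory / f"expr_{cond}_{stage}.tsv"
            pc = directory / f"calls_{cond}_{stage}.tsv"
            ds.values[cols].to_csv(pe, sep="\t", index_label="gene")
            ds.calls[cols].to_csv(pc, sep="\t", index_label="gene")
            written += [pe, pc]
            sample_rows += [(c, cond, stage) for c in cols]

    p = directory / "samples.tsv"
    pd.DataFrame(sample_rows, columns=["sample_id", "condition", "stage"]).to_csv(
        p, sep="\t", index=False
    )
    written.append(p)

    p = directory / "annotations.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("#gene\tgo_id\n")
        for g in truth.proteins:
            for t in sorted(truth.annotations.get(g, ())):
                fh.write(f"{g}\t{t}\n")
    written.append(p)

    cfg = truth.config
    p = directory / "truth.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        flags = [
            f"expressed_{cond}_{t + 1}"
            for cond in CONDITIONS
            for t in range(cfg.n_stages)
        ]
        fh.write("protein\tmodule\t" + "\t".join(flags) + "\n")
        for g in truth.proteins:
            row = [g, str(truth.module_of.get(g, -1))]
            for cond in CONDITIONS:
                for t in range(cfg.n_stages):
                    row.append("1" if g in truth.expressed[cond][t] else "0")
            fh.write("\t".join(row) + "\n")
    written.append(p)
    return written
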