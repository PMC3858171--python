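"""End-to-end orchestration of the two-condition analysis.

The pipeline runs, per condition: expression thresholding -> expressed
PINs -> turnover ratios against the shuffle null -> map-equation module
detection -> lineage tracking; then aligns the two conditions
stage-by-stage to type disease-disrupted lineages, assigns module
functions by interaction-level enrichment, and compares per-stage counts
between conditions with an exact Wilcoxon rank-sum test.  Every
stochastic step is seeded from the single pipeline seed, so a run is a
pure function of (input files, config).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import mannwhitneyu, rankdata

from . import community, disease_calls, enrichment, expression, io_formats, pin_dynamics, tracking
from .errors import ConfigurationError
from .expression import ExpressionConfig
from .tracking import TrackingConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable knobs of the in-memory analysis."""

    expression: ExpressionConfig = ExpressionConfig()
    tracking: TrackingConfig = TrackingConfig()
    method: str = "internal_greedy"
    trials: int = 100
    min_module_size: int = 3
    null_reps: int = 1000
    seed: int = 0


@dataclass
class ResultBundle:
    expressed_counts: dict
    delta_ratios: dict
    null_summaries: dict
    partitions: dict
    lineages: dict
    lineage_summaries: dict
    disruption_calls: list
    disruption_summary: dict
    enrichment: dict
    comparison_p: dict


@dataclass
class PipelineConfig:
    interactions: str
    annotations: str
    samples: str
    conditions: dict  # name -> {"expression": [paths], "calls": [paths]}
    output_dir: str
    interaction_dialect: str = "edge_list"
    annotation_dialect: str = "two_column"
    probe_map: str | None = None
    aging_condition: str = "stable"
    disease_condition: str = "disease"
    threshold: float = 200.0
    require_present: bool = True
    method: str = "internal_greedy"
    trials: int = 100
    min_module_size: int = 3
    cl_threshold: float = 0.5
    cgo_threshold: float = 0.5
    null_reps: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc

    def params(self) -> AnalysisParams:
        return AnalysisParams(
            expression=ExpressionConfig(self.threshold, self.require_present),
            tracking=TrackingConfig(self.cl_threshold, self.cgo_threshold),
            method=self.method,
            trials=self.trials,
            min_module_size=self.min_module_size,
            null_reps=self.null_reps,
            seed=self.seed,
        )


def compare_conditions(counts_a, counts_b) -> float:
    """Exact two-sided Wilcoxon rank-sum p by complete enumeration.

    Midranks handle ties; the two-sided p is 2 * min(tail probabilities),
    capped at 1.  For group sizes outside 2..10 the normal approximation
    is used with a logged warning.
    """
    a = [float(x) for x in counts_a]
    b = [float(x) for x in counts_b]
    n1, n2 = len(a), len(b)
    if not (2 <= n1 <= 10 and 2 <= n2 <= 10):
        log.warning(
            "group sizes %d/%d outside exact-enumeration range; "
            "falling back to the normal approximation",
            n1, n2,
        )
        return float(mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    ranks = rankdata(a + b)
    w_obs = float(np.sum(ranks[:n1]))
    total = comb(n1 + n2, n1)
    eps = 1e-9
    n_le = n_ge = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        w = sum(ranks[i] for i in combo)
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def _condition_analysis(name, ci, interactions, dataset, params):
    """Expression -> PINs -> turnover/null -> partitions for one condition."""
    stages = dataset.stages
    expressed_sets = [
        expression.expressed_set(dataset, s, params.expression) for s in stages
    ]
    pins = [
        pin_dynamics.build_expressed_pin(interactions, es) for es in expressed_sets
    ]
    counts = {
        s: (len(es.genes), len(pin.nodes), len(pin.edges))
        for s, es, pin in zip(stages, expressed_sets, pins)
    }
    for s, (n_expr, n_node, n_edge) in counts.items():
        log.info(
            "%s stage %s: %d expressed genes, PIN %d proteins / %d interactions",
            name, s, n_expr, n_node, n_edge,
        )
    ratios = pin_dynamics.series_delta_ratios(pins)
    null = pin_dynamics.sample_null_ensemble(
        interactions,
        [len(p.edges) for p in pins],
        reps=params.null_reps,
        seed=int(np.random.default_rng([params.seed, 13, ci]).integers(2**31)),
    )
    summaries = {
        "appearing": pin_dynamics.z_score(ratios[0], [r[0] for r in null]),
        "disappearing": pin_dynamics.z_score(ratios[1], [r[1] for r in null]),
    }
    partitions = []
    for t, pin in enumerate(pins):
        det_seed = int(np.random.default_rng([params.seed, 11, ci, t]).integers(2**31))
        part = community.detect_modules(
            pin,
            method=params.method,
            trials=params.trials,
            seed=det_seed,
            min_size=params.min_module_size,
        )
        log.info("%s stage %s: %d modules", name, pin.stage, len(part.modules))
        partitions.append(part)
    return counts, ratios, summaries, pins, partitions


def analyze(
    interactions: io_formats.InteractionSet,
    datasets: dict[str, io_formats.ExpressionDataset],
    annotations: io_formats.AnnotationMap,
    params: AnalysisParams | None = None,
    aging_condition: str = "stable",
    disease_condition: str = "disease",
) -> ResultBundle:
    """In-memory core of the pipeline; see the module docstring for stages."""
    params = params or AnalysisParams()
    names = list(datasets)
    bundle = ResultBundle({}, {}, {}, {}, {}, {}, [], {}, {}, {})
    pins_by_cond = {}
    for ci, name in enumerate(names):
        counts, ratios, summaries, pins, partitions = _condition_analysis(
            name, ci, interactions, datasets[name], params
        )
        bundle.expressed_counts[name] = counts
        bundle.delta_ratios[name] = {"appearing": ratios[0], "disappearing": ratios[1]}
        bundle.null_summaries[name] = summaries
        bundle.partitions[name] = partitions
        pins_by_cond[name] = pins
        lineages = tracking.build_lineages(partitions, annotations, params.tracking)
        bundle.lineages[name] = lineages
        bundle.lineage_summaries[name] = tracking.lineage_summary(lineages)
        per_stage = {}
        for pin, part in zip(pins, partitions):
            iterms = enrichment.annotate_interactions(pin, annotations)
            results = []
            for mod in part.modules:
                results.extend(enrichment.assign_module_functions(mod, iterms))
            per_stage[pin.stage] = results
        bundle.enrichment[name] = per_stage

    if aging_condition in datasets and disease_condition in datasets:
        aging_stages = datasets[aging_condition].stages
        disease_stages = datasets[disease_condition].stages
        disease_calls.align_stages(aging_stages, disease_stages)
        bundle.disruption_calls = disease_calls.call_disruptions(
            bundle.lineages[aging_condition],
            bundle.partitions[aging_condition],
            bundle.partitions[disease_condition],
            annotations,
            params.tracking,
        )
        bundle.disruption_summary = disease_calls.disruption_table(
            bundle.disruption_calls
        )
        a_counts = [bundle.expressed_counts[aging_condition][s] for s in aging_stages]
        d_counts = [bundle.expressed_counts[disease_condition][s] for s in disease_stages]
        bundle.comparison_p = {
            "expressed_proteins": compare_conditions(
                [c[0] for c in a_counts], [c[0] for c in d_counts]
            ),
            "expressed_interactions": compare_conditions(
                [c[2] for c in a_counts], [c[2] for c in d_counts]
            ),
        }
    return bundle


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """File-based entry point: read inputs, analyze, write result TSVs."""
    interactions = io_formats.read_interactions(
        config.interactions, config.interaction_dialect
    )
    annotations = io_formats.read_annotations(
        config.annotations, config.annotation_dialect
    )
    datasets = {}
    for name, files in config.conditions.items():
        ds = io_formats.read_expression(
            files["expression"], files["calls"], config.samples
        )
        if config.probe_map:
            pm = {}
            with open(config.probe_map, encoding="utf-8") as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    probe, gene = line.rstrip("\n").split("\t")[:2]
                    pm[probe] = gene
            ds = expression.collapse_probes(ds, pm)
        datasets[name] = ds
    bundle = analyze(
        interactions,
        datasets,
        annotations,
        config.params(),
        aging_condition=config.aging_condition,
        disease_condition=config.disease_condition,
    )
    io_formats.write_results(bundle, config.output_dir)
    return bundle
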