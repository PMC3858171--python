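"""Probe collapsing and threshold-based expression calls.

A gene is declared expressed in a stage when the mean of its values over
that stage's present-called ('P') samples strictly exceeds the threshold
(default 200 on the linear MAS5-like scale; 150 and 250 are conventional
sensitivity alternates).  Marginal ('M') calls count as not present, and a
gene with no present sample in a stage is unexpressed regardless of its
values.  When several probes measure one gene, the probe with the highest
variance across all samples of the dataset is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, InputError
from .io_formats import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionConfig:
    threshold: float = 200.0
    require_present: bool = True

    def __post_init__(self):
        if self.threshold <= 0:
            raise ConfigurationError("expression threshold must be > 0")


@dataclass(frozen=True)
class ExpressedProteinSet:
    stage: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def collapse_probes(
    dataset: ExpressionDataset, probe_map: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse a probe-level dataset to one row per gene.

    For a gene measured by several probes, the probe whose values have the
    highest variance across *all* samples is retained (its values and calls
    carried over unchanged); exact variance ties go to the
    lexicographically smaller probe id.  Probes absent from ``probe_map``
    are dropped with a logged count.
    """
    if not probe_map:
        raise ConfigurationError("probe_map is empty")
    unmapped = [p for p in dataset.values.index if p not in probe_map]
    if unmapped:
        log.info("dropping %d probes absent from probe_map", len(unmapped))
    variances = dataset.values.var(axis=1, ddof=1)
    best: dict[str, str] = {}  # gene -> probe id
    for probe in dataset.values.index:
        gene = probe_map.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None:
            best[gene] = probe
            continue
        v_new, v_cur = variances[probe], variances[cur]
        if v_new > v_cur or (v_new == v_cur and probe < cur):
            best[gene] = probe
    genes = sorted(best)
    probes = [best[g] for g in genes]
    values = dataset.values.loc[probes].copy()
    calls = dataset.calls.loc[probes].copy()
    values.index = genes
    calls.index = genes
    return ExpressionDataset(values, calls, dict(dataset.sample_stages))


def expressed_set(
    dataset: ExpressionDataset, stage: str, config: ExpressionConfig | None = None
) -> ExpressedProteinSet:
    """Genes expressed in ``stage``: present-sample mean strictly above threshold.

    With ``require_present`` (the default) only samples called 'P' enter
    the mean and a gene needs at least one of them; with it off, all of the
    stage's samples enter the mean.
    """
    config = config or ExpressionConfig()
    samples = dataset.stage_samples(stage)
    if not samples:
        raise InputError(f"stage {stage!r} has no samples")
    values = dataset.values[samples].to_numpy(dtype=float)
    if config.require_present:
        present = dataset.calls[samples].to_numpy() == "P"
        n_present = present.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.where(
                n_present > 0,
                np.where(present, values, 0.0).sum(axis=1) / np.maximum(n_present, 1),
                -np.inf,
            )
        ok = (n_present >= 1) & (means > config.threshold)
    else:
        ok = values.mean(axis=1) > config.threshold
    genes = frozenset(np.asarray(dataset.values.index)[ok].tolist())
    return ExpressedProteinSet(stage=stage, genes=genes)


def expressed_fraction(dataset: ExpressionDataset, sets) -> float:
    """Fraction of the dataset's gene universe expressed in at least one stage."""
    union: set[str] = set()
    for s in sets:
        union |= s.genes
    return len(union) / len(dataset.values.index)
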