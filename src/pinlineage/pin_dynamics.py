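"""Expressed-PIN construction, interaction turnover and the shuffle null.

A stage's expressed PIN is the subgraph of the reference interaction
network induced by that stage's expressed proteins: an interaction is kept
only when both endpoints are expressed at the same time.  Turnover between
consecutive stages is summarized by the pooled ratios of appearing and
disappearing interactions, and compared against an edge-label-shuffle
null: per stage, a uniform random subset of the full interaction universe
of the same size as the observed expressed edge set, drawn independently
across stages and replicates.  Protein-label shuffling and
degree-preserving rewiring are deliberately not offered: the former
shrinks the expected edge count on degree-heterogeneous (scale-free-like)
networks, and the latter invents interactions outside the universe,
deflating the expected turnover either way.

Significance is the z-score (r_obs - mean(r_null)) / sd(r_null) with the
sample (n-1) standard deviation over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DegenerateNullError, InputError
from .expression import ExpressedProteinSet
from .io_formats import Edge, InteractionSet, canonical_edge

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressedPIN:
    """Per-stage expressed protein-interaction network.

    ``nodes`` are the endpoints of retained edges; expressed proteins with
    no expressed interaction partner are kept separately in
    ``isolated_expressed`` so they count as expressed without entering the
    graph.
    """

    stage: str
    nodes: frozenset[str]
    edges: frozenset[Edge]
    isolated_expressed: frozenset[str] = frozenset()

    def graph(self) -> nx.Graph:
        # sorted insertion keeps downstream seeded algorithms independent of
        # Python's per-process set iteration order
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_expressed(self) -> int:
        return len(self.nodes) + len(self.isolated_expressed)


@dataclass(frozen=True)
class DeltaSet:
    transition: tuple[str, str]
    appearing: frozenset[Edge]
    disappearing: frozenset[Edge]


@dataclass(frozen=True)
class NullSummary:
    observed: float
    null_ratios: tuple[float, ...]
    null_mean: float
    null_sd: float
    z: float


def build_expressed_pin(
    interactions: InteractionSet, expressed: ExpressedProteinSet
) -> ExpressedPIN:
    """Induce the expressed PIN: keep edges with both endpoints expressed."""
    if not interactions.pairs:
        log.warning("empty interaction universe; expressed PIN is empty")
    genes = expressed.genes
    edges = frozenset(e for e in interactions.pairs if e[0] in genes and e[1] in genes)
    nodes = frozenset(p for e in edges for p in e)
    universe_proteins = interactions.proteins
    isolated = frozenset(g for g in genes & universe_proteins if g not in nodes)
    return ExpressedPIN(expressed.stage, nodes, edges, isolated)


def interaction_deltas(pin_t: ExpressedPIN, pin_t1: ExpressedPIN) -> DeltaSet:
    """Appearing = E(t+1) \\ E(t); disappearing = E(t) \\ E(t+1)."""
    return DeltaSet(
        transition=(pin_t.stage, pin_t1.stage),
        appearing=pin_t1.edges - pin_t.edges,
        disappearing=pin_t.edges - pin_t1.edges,
    )


def series_delta_ratios(pins) -> tuple[float, float]:
    """Pooled appearing/disappearing ratios over an ordered PIN series.

    Appearing interactions are normalized by the later stage's edge count
    and disappearing by the earlier stage's, summed over all consecutive
    transitions, so each ratio lies in [0, 1] and reads as the fraction of
    a stage's interactions that are new (resp. lost).
    """
    pins = list(pins)
    if len(pins) < 2:
        raise InputError("need at least two stages to compute delta ratios")
    app_num = dis_num = app_den = dis_den = 0
    for a, b in zip(pins, pins[1:]):
        d = interaction_deltas(a, b)
        app_num += len(d.appearing)
        dis_num += len(d.disappearing)
        app_den += len(b.edges)
        dis_den += len(a.edges)
    if app_den == 0 or dis_den == 0:
        raise InputError("delta ratio undefined: a stage has no expressed interactions")
    return app_num / app_den, dis_num / dis_den


def sample_null_ensemble(
    universe: InteractionSet,
    sizes,
    reps: int = 1000,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Edge-label-shuffle null for the appearing/disappearing ratios.

    Per replicate and per stage an independent uniform random subset of
    the interaction universe with the observed stage's edge count is
    drawn; ratios are pooled exactly as in :func:`series_delta_ratios`.
    """
    sizes = [int(s) for s in sizes]
    n_univ = len(universe.pairs)
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if len(sizes) < 2:
        raise ConfigurationError("need at least two per-stage sizes")
    if any(s < 0 or s > n_univ for s in sizes):
        raise ConfigurationError(
            f"per-stage sizes must be within [0, {n_univ}], got {sizes}"
        )
    rng = np.random.default_rng(seed)
    app_den = sum(sizes[1:])
    dis_den = sum(sizes[:-1])
    if app_den == 0 or dis_den == 0:
        raise ConfigurationError("null ratios undefined for all-zero stage sizes")
    out: list[tuple[float, float]] = []
    for _ in range(reps):
        masks = []
        for s in sizes:
            m = np.zeros(n_univ, dtype=bool)
            m[rng.choice(n_univ, size=s, replace=False)] = True
            masks.append(m)
        app = sum(int((b & ~a).sum()) for a, b in zip(masks, masks[1:]))
        dis = sum(int((a & ~b).sum()) for a, b in zip(masks, masks[1:]))
        out.append((app / app_den, dis / dis_den))
    return out


def z_score(observed: float, null_ratios) -> NullSummary:
    """Eq-1-style z-score of an observed ratio against null replicates."""
    null_ratios = [float(r) for r in null_ratios]
    if len(null_ratios) < 2:
        raise InputError("need at least two null replicates for a z-score")
    mean = float(np.mean(null_ratios))
    sd = float(np.std(null_ratios, ddof=1))
    if sd == 0.0:
        raise DegenerateNullError("null replicate ratios are all equal; z undefined")
    return NullSummary(
        observed=float(observed),
        null_ratios=tuple(null_ratios),
        null_mean=mean,
        null_sd=sd,
        z=(float(observed) - mean) / sd,
    )
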