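"""Module auto-correlation, inherited pairs and lineage assembly.

Two modules in consecutive stages are compared by the Jaccard index of
their protein sets (C_N), induced-interaction sets (C_L) and GO
biological-process term sets (C_GO).  Across all cross-stage module
pairs, a pair is a candidate link when each module is the other's best
match by C_L (mutual best), and the link is "inherited" when both C_L
and C_GO strictly exceed 0.5 (thresholds configurable; 0.3-0.7 is the
conventional sensitivity range).  Maximal chains of inherited links form
lineages; a lineage spanning the first through last stage is itself
called inherited, one starting later is appearing, one ending early is
disappearing, and one that starts at the first stage but breaks before
the end is disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .community import Module, ModulePartition
from .errors import InputError
from .io_formats import AnnotationMap


@dataclass(frozen=True)
class TrackingConfig:
    cl_threshold: float = 0.5
    cgo_threshold: float = 0.5


@dataclass(frozen=True)
class ModuleMatch:
    module_t: Module
    module_t1: Module
    c_n: float
    c_l: float
    c_go: float
    inherited: bool


@dataclass(frozen=True)
class Lineage:
    """A maximal chain of modules linked by inherited matches.

    ``chain`` holds (stage index, module id) in strictly increasing,
    consecutive stage order; ``size`` is the number of distinct proteins
    in the union over the chain.
    """

    chain: tuple[tuple[int, int], ...]
    status: str  # inherited | appearing | disappearing | disrupted
    transitions: tuple[ModuleMatch, ...]
    proteins: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.proteins)


def autocorrelation(set_a, set_b) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both sets are empty.

    The both-empty convention means "this feature did not change", so a
    comparison on e.g. GO terms of two unannotated modules is decided by
    the other feature sets.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def module_feature_sets(module: Module, annotations: AnnotationMap):
    """(protein set, interaction set, GO BP term union) of a module."""
    go: set[str] = set()
    for p in module.proteins:
        go |= annotations.get(p, frozenset())
    return module.proteins, module.edges, frozenset(go)


def _match(
    m_t: Module, m_t1: Module, annotations: AnnotationMap, config: TrackingConfig
) -> ModuleMatch:
    _, e_t, g_t = module_feature_sets(m_t, annotations)
    _, e_t1, g_t1 = module_feature_sets(m_t1, annotations)
    c_n = autocorrelation(m_t.proteins, m_t1.proteins)
    c_l = autocorrelation(e_t, e_t1)
    c_go = autocorrelation(g_t, g_t1)
    return ModuleMatch(
        m_t,
        m_t1,
        c_n,
        c_l,
        c_go,
        inherited=c_l > config.cl_threshold and c_go > config.cgo_threshold,
    )


def mutual_best_pairs(
    p_t: ModulePartition,
    p_t1: ModulePartition,
    annotations: AnnotationMap,
    config: TrackingConfig | None = None,
) -> list[ModuleMatch]:
    """Mutual-best module pairs by C_L between two consecutive partitions.

    C_L is computed for every cross pair; a pair is retained when each
    member is the other's best match (ties broken by C_N, then C_GO, then
    the smallest member symbol, so output is deterministic).
    """
    config = config or TrackingConfig()
    if not p_t.modules or not p_t1.modules:
        return []
    matches = {
        (a.id, b.id): _match(a, b, annotations, config)
        for a in p_t.modules
        for b in p_t1.modules
    }
    fwd: dict[int, ModuleMatch] = {}
    for a in p_t.modules:
        fwd[a.id] = max(
            (matches[(a.id, b.id)] for b in p_t1.modules),
            key=lambda m: (m.c_l, m.c_n, m.c_go, min(m.module_t1.proteins)),
        )
    bwd: dict[int, ModuleMatch] = {}
    for b in p_t1.modules:
        bwd[b.id] = max(
            (matches[(a.id, b.id)] for a in p_t.modules),
            key=lambda m: (m.c_l, m.c_n, m.c_go, min(m.module_t.proteins)),
        )
    retained = []
    for a in p_t.modules:
        m = fwd[a.id]
        if bwd[m.module_t1.id].module_t.id == a.id:
            retained.append(m)
    return retained


def build_lineages(
    partitions,
    annotations: AnnotationMap,
    config: TrackingConfig | None = None,
) -> list[Lineage]:
    """Assemble lineages from inherited mutual-best links across stages.

    Every module belongs to exactly one lineage (possibly a singleton
    chain).  Status follows the chain's span: the full first-to-last range
    -> inherited; anchored at the first stage but broken before the end ->
    disrupted; starting late and surviving to the end -> appearing; broken
    before the end after a late start -> disappearing.
    """
    partitions = list(partitions)
    if len(partitions) < 2:
        raise InputError("need at least two stage partitions to build lineages")
    config = config or TrackingConfig()
    n_stages = len(partitions)
    links: dict[tuple[int, int], ModuleMatch] = {}
    for t in range(n_stages - 1):
        for m in mutual_best_pairs(partitions[t], partitions[t + 1], annotations, config):
            if m.inherited:
                links[(t, m.module_t.id)] = m
    linked_into = {
        (t + 1, m.module_t1.id) for (t, _), m in links.items()
    }
    module_by = {
        (t, mod.id): mod
        for t, part in enumerate(partitions)
        for mod in part.modules
    }
    lineages: list[Lineage] = []
    for t, part in enumerate(partitions):
        for mod in part.modules:
            if (t, mod.id) in linked_into:
                continue  # continuation of an earlier chain
            chain = [(t, mod.id)]
            transitions: list[ModuleMatch] = []
            proteins = set(mod.proteins)
            cur = (t, mod.id)
            while cur in links:
                m = links[cur]
                nxt = (cur[0] + 1, m.module_t1.id)
                chain.append(nxt)
                transitions.append(m)
                proteins |= m.module_t1.proteins
                cur = nxt
            first, last = chain[0][0], chain[-1][0]
            if first == 0 and last == n_stages - 1:
                status = "inherited"
            elif first == 0:
                status = "disrupted"
            elif last == n_stages - 1:
                status = "appearing"
            else:
                status = "disappearing"
            lineages.append(
                Lineage(tuple(chain), status, tuple(transitions), frozenset(proteins))
            )
    return lineages


def lineage_summary(lineages) -> dict:
    """Counts, ratios and median sizes per lineage status.

    Also reports the ratio of the median inherited-lineage size to the
    median size over appearing and disappearing lineages combined (the
    conventional stability-vs-size comparison), when both exist.
    """
    import numpy as np

    lineages = list(lineages)
    statuses = ("inherited", "appearing", "disappearing", "disrupted")
    out: dict = {"total": len(lineages), "counts": {}, "ratios": {}, "median_size": {}}
    if not lineages:
        return out
    for s in statuses:
        group = [l for l in lineages if l.status == s]
        out["counts"][s] = len(group)
        out["ratios"][s] = len(group) / len(lineages)
        out["median_size"][s] = float(np.median([l.size for l in group])) if group else None
    trans = [l.size for l in lineages if l.status in ("appearing", "disappearing")]
    inh = [l.size for l in lineages if l.status == "inherited"]
    if inh and trans:
        out["inherited_vs_transient_size_ratio"] = float(
            np.median(inh) / np.median(trans)
        )
    return out
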