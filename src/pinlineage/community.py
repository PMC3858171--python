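"""Map-equation module detection on expressed PINs.

The two-level map equation scores a partition M of an undirected,
unweighted network by the expected per-step description length of a
random walker's trajectory,

    L(M) = q H(Q) + sum_i p_i H(P_i)   [bits],

with stationary visit rates proportional to degree (p_a = k_a / 2m, no
teleportation), module exit probabilities q_i = cut_i / 2m, q = sum q_i,
H(Q) the entropy of the module-index codebook and H(P_i) the entropy of
module i's within-module codebook (its member visit rates plus its exit
rate).  Minimizing L over partitions yields both the module assignment
and the number of modules.

The required optimizer is self-contained: Louvain-style local node moves
scored by exact map-equation deltas, followed by module aggregation and
refinement, restarted ``trials`` times from random orders with the
best-scoring partition kept (the paper-scale convention is 1,000 trials;
the package default is 100).  External backends (igraph's compiled
Infomap, igraph's Louvain) can be plugged in when python-igraph is
importable; their candidate partitions are still selected by this
module's own map-equation value.  Modules with fewer than ``min_size``
proteins (default 3) are filtered out and their members reported as
unassigned; filtered members are excluded from all downstream tracking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError, InputError
from .io_formats import Edge, canonical_edge

__all__ = [
    "Module",
    "ModulePartition",
    "map_equation",
    "detect_modules",
    "brute_force_partition",
    "METHODS",
]

METHODS = ("internal_greedy", "infomap_backend", "louvain_backend")


@dataclass(frozen=True)
class Module:
    id: int
    proteins: frozenset[str]
    edges: frozenset[Edge]

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class ModulePartition:
    stage: str
    modules: tuple[Module, ...]
    unassigned: frozenset[str] = frozenset()

    def membership(self) -> dict[str, int]:
        return {p: m.id for m in self.modules for p in m.proteins}

    def __len__(self) -> int:
        return len(self.modules)


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


def _as_graph(pin) -> nx.Graph:
    if isinstance(pin, nx.Graph):
        return pin
    return pin.graph()


def map_equation(pin, partition) -> float:
    """Two-level map equation L(M) in bits for a node -> module mapping.

    ``partition`` must cover every node of the graph.  An edgeless graph
    has description length 0 by convention.
    """
    g = _as_graph(pin)
    missing = [v for v in g.nodes if v not in partition]
    if missing:
        raise InputError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    two_m = 2.0 * m
    # per-module exit weight (edges crossing the boundary) and visit mass
    cut: dict = {}
    mass: dict = {}
    for v in g.nodes:
        i = partition[v]
        mass[i] = mass.get(i, 0.0) + g.degree(v) / two_m
        cut.setdefault(i, 0.0)
    for a, b in g.edges:
        ia, ib = partition[a], partition[b]
        if ia != ib:
            cut[ia] += 1.0 / two_m
            cut[ib] += 1.0 / two_m
    q = sum(cut.values())
    L = _plogp(q)
    for i in cut:
        L -= 2.0 * _plogp(cut[i])
        L += _plogp(cut[i] + mass[i])
    for v in g.nodes:
        L -= _plogp(g.degree(v) / two_m)
    return L


# ---------------------------------------------------------------------------
# internal greedy optimizer
#
# Works on a weighted adjacency with separate self-loop weights so module
# aggregation is exact.  Only the partition-dependent part of L,
#     f(q) - 2 sum_i f(q_i) + sum_i f(q_i + s_i),      f(x) = x log2 x,
# is tracked; the node-rate term is constant and added back by
# map_equation when scoring the final partition.


class _State:
    __slots__ = ("adj", "loop", "two_m", "p", "ext", "module", "mod_q", "mod_s",
                 "mod_n", "sum_q")

    def __init__(self, adj, loop):
        self.adj = adj
        self.loop = loop
        self.two_m = sum(sum(nb.values()) for nb in adj.values()) + 2.0 * sum(
            loop.values()
        )
        self.p = {}
        self.ext = {}
        for v, nb in adj.items():
            k_ext = sum(nb.values())
            self.p[v] = (k_ext + 2.0 * loop[v]) / self.two_m
            self.ext[v] = k_ext / self.two_m
        self.module = {v: v for v in adj}
        self.mod_q = {v: self.ext[v] for v in adj}
        self.mod_s = {v: self.p[v] for v in adj}
        self.mod_n = {v: 1 for v in adj}
        self.sum_q = sum(self.mod_q.values())

    def partition_cost(self) -> float:
        c = _plogp(self.sum_q)
        for i, qi in self.mod_q.items():
            c += -2.0 * _plogp(qi) + _plogp(qi + self.mod_s[i])
        return c

    def set_partition(self, part):
        self.module = dict(part)
        mod_q: dict = {}
        mod_s: dict = {}
        mod_n: dict = {}
        for v in self.adj:
            i = self.module[v]
            mod_s[i] = mod_s.get(i, 0.0) + self.p[v]
            mod_n[i] = mod_n.get(i, 0) + 1
            mod_q.setdefault(i, 0.0)
        for v, nb in self.adj.items():
            iv = self.module[v]
            for u, w in nb.items():
                if self.module[u] != iv:
                    mod_q[iv] += w / self.two_m
        self.mod_q, self.mod_s, self.mod_n = mod_q, mod_s, mod_n
        self.sum_q = sum(mod_q.values())

    def local_moves(self, rng) -> bool:
        """Sweep nodes in random order until no improving move; True if any."""
        nodes = list(self.adj)
        improved_any = False
        for _sweep in range(200):
            moved = 0
            order = rng.permutation(len(nodes))
            for idx in order:
                v = nodes[idx]
                if self._best_move(v):
                    moved += 1
            if moved:
                improved_any = True
            else:
                break
        return improved_any

    def _best_move(self, v) -> bool:
        i = self.module[v]
        # weight from v to each neighboring module
        w_to: dict = {}
        for u, w in self.adj[v].items():
            j = self.module[u]
            w_to[j] = w_to.get(j, 0.0) + w
        w_vi = w_to.get(i, 0.0)
        pv, extv = self.p[v], self.ext[v]
        qi, si = self.mod_q[i], self.mod_s[i]
        qi_new = qi - extv + 2.0 * w_vi / self.two_m
        base_i = (-2.0 * _plogp(qi) + _plogp(qi + si)) - (
            -2.0 * _plogp(qi_new) + _plogp(qi_new + si - pv)
        )
        best_delta = -1e-12
        best_j = None
        best_qj_new = 0.0
        candidates = [j for j in w_to if j != i]
        if self.mod_n[i] > 1:
            candidates.append(None)  # fresh singleton module
        for j in candidates:
            if j is None:
                qj, sj, w_vj = 0.0, 0.0, 0.0
            else:
                qj, sj = self.mod_q[j], self.mod_s[j]
                w_vj = w_to.get(j, 0.0)
            qj_new = qj + extv - 2.0 * w_vj / self.two_m
            dq = (qi_new + qj_new) - (qi + qj)
            delta = (
                _plogp(self.sum_q + dq)
                - _plogp(self.sum_q)
                - base_i
                - 2.0 * _plogp(qj_new)
                + _plogp(qj_new + sj + pv)
                + 2.0 * _plogp(qj)
                - _plogp(qj + sj)
            )
            if delta < best_delta:
                best_delta, best_j, best_qj_new = delta, j, qj_new
        if best_j is None and best_delta >= -1e-12:
            return False
        j = best_j
        if j is None:
            j = object()  # fresh module key
            self.mod_q[j] = 0.0
            self.mod_s[j] = 0.0
            self.mod_n[j] = 0
        # apply
        self.sum_q += (qi_new + best_qj_new) - (qi + self.mod_q[j])
        self.mod_q[i] = qi_new
        self.mod_s[i] = si - pv
        self.mod_n[i] -= 1
        if self.mod_n[i] == 0:
            del self.mod_q[i], self.mod_s[i], self.mod_n[i]
        self.mod_q[j] = best_qj_new
        self.mod_s[j] = self.mod_s[j] + pv
        self.mod_n[j] += 1
        self.module[v] = j
        return True


def _aggregate(adj, loop, part):
    """Collapse modules to super-nodes; intra-module weight becomes loops."""
    new_adj: dict = {}
    new_loop: dict = {}
    for v in adj:
        i = part[v]
        new_adj.setdefault(i, {})
        new_loop[i] = new_loop.get(i, 0.0) + loop[v]
    for v, nb in adj.items():
        iv = part[v]
        for u, w in nb.items():
            iu = part[u]
            if iv == iu:
                # each intra-module edge appears in both directions
                new_loop[iv] = new_loop.get(iv, 0.0) + w / 2.0
            else:
                new_adj[iv][iu] = new_adj[iv].get(iu, 0.0) + w
    return new_adj, new_loop


def _greedy_once(adj, loop, rng) -> dict:
    """One multi-level optimization run; returns node -> module label."""
    node_to_orig = {v: frozenset([v]) for v in adj}
    cur_adj, cur_loop = adj, loop
    final: dict = {v: v for v in adj}
    while True:
        state = _State(cur_adj, cur_loop)
        improved = state.local_moves(rng)
        part = state.module
        n_modules = len(set(part.values()))
        # record assignment of original nodes
        label_of: dict = {}
        for v, lab in part.items():
            for orig in node_to_orig[v]:
                label_of[orig] = lab
        final = label_of
        if not improved or n_modules == len(cur_adj):
            break
        cur_adj, cur_loop = _aggregate(cur_adj, cur_loop, part)
        merged: dict = {}
        for v, lab in part.items():
            merged.setdefault(lab, set()).update(node_to_orig[v])
        node_to_orig = {lab: frozenset(s) for lab, s in merged.items()}
    # final node-level refinement on the original graph
    state = _State(adj, loop)
    state.set_partition(final)
    state.local_moves(rng)
    return dict(state.module)


def _partition_cost(adj, loop, part) -> float:
    state = _State(adj, loop)
    state.set_partition(part)
    return state.partition_cost()


def _canonical(part) -> tuple:
    groups: dict = {}
    for v, lab in part.items():
        groups.setdefault(lab, []).append(v)
    return tuple(sorted(tuple(sorted(map(str, g))) for g in groups.values()))


def _run_internal(graph: nx.Graph, trials: int, seed) -> dict:
    # deterministic construction order regardless of caller's node order
    nodes = sorted(graph.nodes, key=str)
    adj = {v: {} for v in nodes}
    loop = {v: 0.0 for v in nodes}
    for a, b in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        adj[a][b] = adj[a].get(b, 0.0) + 1.0
        adj[b][a] = adj[b].get(a, 0.0) + 1.0
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=trials)
    best = None
    for s in seeds:
        part = _greedy_once(adj, loop, np.random.default_rng(int(s)))
        cost = _partition_cost(adj, loop, part)
        key = (round(cost, 12), _canonical(part))
        if best is None or key < best[0]:
            best = (key, part)
    return best[1]


def _run_igraph(graph: nx.Graph, trials: int, seed, method: str) -> dict:
    try:
        import igraph as ig
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ConfigurationError(
            f"method {method!r} requires python-igraph"
        ) from exc
    import random as _random

    nodes = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[a], index[b]) for a, b in graph.edges]
    )
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=trials)
    best = None
    for s in seeds:
        ig.set_random_number_generator(_random.Random(int(s)))
        if method == "infomap_backend":
            clu = g.community_infomap(trials=1)
        else:
            clu = g.community_multilevel()
        part = {nodes[i]: lab for i, lab in enumerate(clu.membership)}
        cost = map_equation(graph, part)
        key = (round(cost, 12), _canonical(part))
        if best is None or key < best[0]:
            best = (key, part)
    ig.set_random_number_generator(None)
    return best[1]


def detect_modules(
    pin,
    method: str = "internal_greedy",
    trials: int = 100,
    seed: int | None = None,
    min_size: int = 3,
) -> ModulePartition:
    """Partition an expressed PIN into modules by map-equation minimization.

    The optimizer is restarted ``trials`` times from seeds derived from
    ``seed`` and the minimum-L partition kept (ties broken by canonical
    form, so output is deterministic given the seed).  Modules smaller
    than ``min_size`` are dropped; their members are returned as
    unassigned and take no part in downstream tracking.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown detection method {method!r}")
    if trials < 1:
        raise ConfigurationError("trials must be >= 1")
    graph = _as_graph(pin)
    stage = getattr(pin, "stage", "")
    if graph.number_of_edges() == 0:
        return ModulePartition(stage, (), frozenset(graph.nodes))
    if method == "internal_greedy":
        part = _run_internal(graph, trials, seed)
    else:
        part = _run_igraph(graph, trials, seed, method)
    groups: dict = {}
    for v, lab in part.items():
        groups.setdefault(lab, set()).add(v)
    kept = [g for g in groups.values() if len(g) >= min_size]
    unassigned = frozenset(
        v for g in groups.values() if len(g) < min_size for v in g
    )
    kept.sort(key=lambda g: (-len(g), min(g)))
    modules = []
    for i, members in enumerate(kept, start=1):
        edges = frozenset(
            canonical_edge(a, b)
            for a, b in graph.edges(members)
            if a in members and b in members
        )
        modules.append(Module(id=i, proteins=frozenset(members), edges=edges))
    return ModulePartition(stage, tuple(modules), unassigned)


# ---------------------------------------------------------------------------
# brute-force oracle for small graphs


def _set_partitions(items):
    """All set partitions of ``items`` (restricted growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_force_partition(graph: nx.Graph, max_nodes: int = 10):
    """Exhaustive map-equation minimum over all set partitions.

    Intended as an independent oracle on tiny graphs; refuses graphs with
    more than ``max_nodes`` nodes (Bell numbers explode).
    Returns ``(best_L_bits, node -> module dict)``.
    """
    if graph.number_of_nodes() > max_nodes:
        raise InputError(
            f"brute force limited to {max_nodes} nodes; got "
            f"{graph.number_of_nodes()}"
        )
    best = None
    for blocks in _set_partitions(sorted(graph.nodes, key=str)):
        part = {v: i for i, block in enumerate(blocks) for v in block}
        L = map_equation(graph, part)
        key = (round(L, 12), _canonical(part))
        if best is None or key < best[0]:
            best = (key, L, part)
    return best[1], best[2]
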