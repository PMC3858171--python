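"""Interaction-level GO biological-process enrichment of modules.

An interaction is annotated with the GO BP terms shared by *both* of its
endpoint proteins; interactions whose endpoints share no term are
unannotated and excluded from the background.  For a module and a term,
with x = annotated module interactions carrying the term, m = annotated
module interactions, n = annotated interactions carrying the term
network-wide and N = annotated interactions network-wide, significance
is the upper-tail hypergeometric probability P(X >= x) of drawing m
interactions from N of which n carry the term, and effect size is the
fold enrichment ratio FER = (x/m)/(n/N).  A term is assigned to the
module when p < 0.05 and FER > 2 (both strict); p-values are raw by
convention, with optional Benjamini-Hochberg correction as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy.stats import hypergeom

from .community import Module
from .errors import InputError
from .io_formats import AnnotationMap, Edge
from .pin_dynamics import ExpressedPIN

P_CUTOFF = 0.05
FER_CUTOFF = 2.0


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: int
    term: str
    x: int
    m: int
    n: int
    N: int
    p: float
    fer: float
    assigned: bool


def annotate_interactions(
    pin: ExpressedPIN, annotations: AnnotationMap, term_collapse: Mapping[str, str] | None = None
) -> dict[Edge, frozenset[str]]:
    """Map each expressed interaction to the terms common to both endpoints.

    ``term_collapse`` optionally maps fine-grained term ids onto curated
    umbrella terms (identity when omitted).  Interactions with an empty
    endpoint-term intersection are omitted from the result.
    """
    out: dict[Edge, frozenset[str]] = {}
    for a, b in pin.edges:
        shared = annotations.get(a, frozenset()) & annotations.get(b, frozenset())
        if term_collapse:
            shared = frozenset(term_collapse.get(t, t) for t in shared)
        if shared:
            out[(a, b) if a <= b else (b, a)] = frozenset(shared)
    return out


def hypergeom_tail(x: int, m: int, n: int, N: int) -> float:
    """Upper-tail P(X >= x) for drawing m from N containing n successes."""
    if not (0 <= x <= min(m, n)) or m > N or n > N or min(m, n, N) < 0:
        raise InputError(f"inconsistent hypergeometric counts x={x} m={m} n={n} N={N}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, n, m))


def fold_enrichment(x: int, m: int, n: int, N: int) -> float:
    """Fold enrichment ratio (x/m)/(n/N)."""
    if m <= 0 or n <= 0:
        raise InputError("fold enrichment needs m > 0 and n > 0")
    return (x / m) / (n / N)


def assign_module_functions(
    module: Module,
    interaction_terms: Mapping[Edge, frozenset[str]],
    background: Mapping[Edge, frozenset[str]] | None = None,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment of every term carried by a module's interactions.

    ``interaction_terms`` is the network-wide interaction -> term map from
    :func:`annotate_interactions` (``background`` may override it when the
    module map is a subset view).  Results are sorted by p ascending, ties
    by term id.  A module with no annotated interaction yields [].
    """
    background = background if background is not None else interaction_terms
    N = len(background)
    if N == 0:
        raise InputError("background has no annotated interactions")
    n_of: dict[str, int] = {}
    for terms in background.values():
        for t in terms:
            n_of[t] = n_of.get(t, 0) + 1
    mod_edges = [e for e in module.edges if e in background]
    m = len(mod_edges)
    if m == 0:
        return []
    x_of: dict[str, int] = {}
    for e in mod_edges:
        for t in background[e]:
            x_of[t] = x_of.get(t, 0) + 1
    results = []
    for term, x in x_of.items():
        n = n_of[term]
        p = hypergeom_tail(x, m, n, N)
        fer = fold_enrichment(x, m, n, N)
        results.append(
            EnrichmentResult(
                module.id, term, x, m, n, N, p, fer,
                assigned=p < P_CUTOFF and fer > FER_CUTOFF,
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    if bh_correct:
        import numpy as np

        k = len(results)
        ps = np.array([r.p for r in results])
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        prev = 1.0
        for i in range(k - 1, -1, -1):
            idx = order[i]
            prev = min(prev, ps[idx] * k / (i + 1))
            adj[idx] = prev
        results = [
            EnrichmentResult(
                r.module_id, r.term, r.x, r.m, r.n, r.N, r.p, r.fer,
                assigned=adj[i] < P_CUTOFF and r.fer > FER_CUTOFF,
            )
            for i, r in enumerate(results)
        ]
    return results
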