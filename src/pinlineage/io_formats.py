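"""Readers and writers for the file formats the pipeline touches.

Interactions come either as a BioGRID-style tab file (header row, official
gene-symbol columns located by name so both TAB2-era and tab3 headers work)
or as a plain two-column edge list.  Expression data is a genes x samples
TSV matrix with a matching P/M/A detection-call matrix and a sample
metadata table mapping each sample to a condition and an ordered stage.
Annotations come as GAF 2.x (only aspect 'P', biological process, is kept)
or as a two-column gene/term TSV.

All TSVs are UTF-8, tab-delimited; lines starting with '#' are ignored.
Identifiers are official gene symbols end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, SchemaError

log = logging.getLogger(__name__)

Edge = tuple[str, str]

#: BioGRID official-symbol column names across format generations.
_BIOGRID_SYMBOL_COLS = [
    ("Official Symbol Interactor A", "Official Symbol Interactor B"),
    ("OFFICIAL_SYMBOL_A", "OFFICIAL_SYMBOL_B"),
]

VALID_CALLS = frozenset({"P", "M", "A"})


def canonical_edge(a: str, b: str) -> Edge:
    """Order-independent key for an undirected interaction."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionSet:
    """Undirected protein pairs keyed by official gene symbol.

    Self-pairs and symmetric duplicates are removed at construction.
    """

    pairs: frozenset[Edge]
    source: str | None = None
    n_dropped_self: int = 0
    n_dropped_duplicate: int = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], source: str | None = None):
        seen: set[Edge] = set()
        n_self = n_dup = 0
        for a, b in pairs:
            if a == b:
                n_self += 1
                continue
            e = canonical_edge(a, b)
            if e in seen:
                n_dup += 1
            else:
                seen.add(e)
        return cls(frozenset(seen), source, n_self, n_dup)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for e in self.pairs for p in e)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return canonical_edge(*edge) in self.pairs


@dataclass
class ExpressionDataset:
    """Expression matrix (linear MAS5-like scale) with its P/M/A call mask.

    ``values`` and ``calls`` share index (probe or gene ids) and columns
    (sample ids); ``sample_stages`` maps every sample to exactly one stage.
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    sample_stages: dict[str, str]

    def __post_init__(self):
        if self.values.shape != self.calls.shape:
            raise SchemaError(
                f"expression {self.values.shape} and calls {self.calls.shape} "
                "matrices have different shapes"
            )
        if list(self.values.index) != list(self.calls.index) or list(
            self.values.columns
        ) != list(self.calls.columns):
            raise SchemaError("expression and call matrices have different ids")
        bad = set(self.calls.to_numpy().ravel()) - VALID_CALLS
        if bad:
            raise ParseError(f"unknown detection-call symbols: {sorted(bad)!r}")
        missing = [s for s in self.values.columns if s not in self.sample_stages]
        if missing:
            raise SchemaError(f"samples missing from metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance (i.e. metadata) order."""
        out: list[str] = []
        for s in self.values.columns:
            st = self.sample_stages[s]
            if st not in out:
                out.append(st)
        return out

    def stage_samples(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_stages[s] == stage]


AnnotationMap = dict[str, frozenset[str]]


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: Path):
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            yield i, line.rstrip("\n")


def read_interactions(path, dialect: str = "edge_list") -> InteractionSet:
    """Read an interaction table into an :class:`InteractionSet`.

    ``dialect`` is ``"biogrid_tab"`` (header row; official-symbol columns
    found by name) or ``"edge_list"`` (two symbol columns, no header
    required).  Self-interactions are dropped and symmetric duplicates
    collapsed; the dropped counts are logged and kept on the result.
    """
    path = Path(path)
    if dialect not in ("biogrid_tab", "edge_list"):
        raise ParseError(f"unknown interaction dialect {dialect!r}")
    pairs: list[tuple[str, str]] = []
    if dialect == "biogrid_tab":
        # BioGRID headers conventionally start with '#'; keep the first
        # non-empty line as the header before comment-skipping the rest
        with open(path, encoding="utf-8") as fh:
            raw = [
                (i, line.rstrip("\n"))
                for i, line in enumerate(fh, start=1)
                if line.strip()
            ]
        if not raw:
            log.warning("empty interaction file %s", path)
            return InteractionSet(frozenset(), str(path))
        lines = [raw[0]] + [(i, l) for i, l in raw[1:] if not l.startswith("#")]
        header = lines[0][1].lstrip("#").split("\t")
        cols = None
        for ca, cb in _BIOGRID_SYMBOL_COLS:
            if ca in header and cb in header:
                cols = (header.index(ca), header.index(cb))
                break
        if cols is None:
            raise ParseError(
                "no official-symbol columns found in BioGRID header",
                path,
                lines[0][0],
            )
        for lineno, line in lines[1:]:
            f = line.split("\t")
            if len(f) <= max(cols):
                raise ParseError("truncated BioGRID row", path, lineno)
            pairs.append((f[cols[0]], f[cols[1]]))
    else:
        for lineno, line in _data_lines(path):
            f = line.split("\t")
            if len(f) < 2 or not f[0] or not f[1]:
                raise ParseError("edge-list row needs two symbols", path, lineno)
            pairs.append((f[0], f[1]))
    out = InteractionSet.from_pairs(pairs, source=str(path))
    if not out.pairs:
        log.warning("interaction set from %s is empty", path)
    if out.n_dropped_self or out.n_dropped_duplicate:
        log.info(
            "%s: dropped %d self-interactions, %d duplicate pairs",
            path,
            out.n_dropped_self,
            out.n_dropped_duplicate,
        )
    return out


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate entity rows in {path}: {dups[:5]}")
    return df


def read_samples(path) -> pd.DataFrame:
    """Read sample metadata: columns sample_id, condition, stage."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "condition", "stage"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"samples table {path} must have columns {sorted(required)}"
        )
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"duplicate sample_id rows in {path}")
    return df


def read_expression(expr_path, calls_path, samples_path) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from its three files.

    ``expr_path`` / ``calls_path`` may each be one path or a sequence of
    per-stage paths; per-stage matrices are concatenated column-wise and
    must share the same gene index.
    """
    def as_list(p):
        return [p] if isinstance(p, (str, Path)) else list(p)

    expr_parts = [_read_matrix(p) for p in as_list(expr_path)]
    call_parts = [_read_matrix(p) for p in as_list(calls_path)]
    for part in expr_parts[1:] + call_parts:
        if list(part.index) != list(expr_parts[0].index):
            raise SchemaError("gene rows differ between expression/call files")
    values = pd.concat(expr_parts, axis=1)
    calls = pd.concat(call_parts, axis=1)
    samples = read_samples(samples_path)
    stage_of = dict(zip(samples["sample_id"], samples["stage"]))
    missing = [s for s in values.columns if s not in stage_of]
    if missing:
        raise SchemaError(f"samples absent from metadata table: {missing}")
    return ExpressionDataset(values, calls, {s: stage_of[s] for s in values.columns})


def read_annotations(path, dialect: str = "two_column") -> AnnotationMap:
    """Read gene -> GO biological-process term-set annotations.

    ``"gaf"`` keeps only aspect-'P' rows of a GAF 2.x file, keyed by the
    DB-object-symbol column; ``"two_column"`` reads gene<TAB>term rows.
    Genes with no rows are simply absent from the map.
    """
    path = Path(path)
    if dialect not in ("gaf", "two_column"):
        raise ParseError(f"unknown annotation dialect {dialect!r}")
    acc: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        if dialect == "gaf":
            if line.startswith("!"):
                continue
            f = line.split("\t")
            if len(f) < 15:
                raise ParseError("GAF row has fewer than 15 columns", path, lineno)
            symbol, term, aspect = f[2], f[4], f[8]
            if aspect != "P":
                continue
        else:
            f = line.split("\t")
            if len(f) < 2 or not f[0] or not f[1]:
                raise ParseError("annotation row needs gene and term", path, lineno)
            symbol, term = f[0], f[1]
        acc.setdefault(symbol, set()).add(term)
    return {g: frozenset(t) for g, t in acc.items()}


# ---------------------------------------------------------------------------
# result writers

_FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_results(bundle, directory) -> list[Path]:
    """Write a :class:`~pinlineage.pipeline.ResultBundle` as a set of TSVs.

    Files written: ``modules.tsv`` (condition, stage, module id, gene),
    ``lineages.tsv`` (one row per lineage with per-transition C_N/C_L/C_GO),
    ``disruption_calls.tsv``, ``delta_ratios.tsv`` (observed ratios with
    null mean/sd and z), ``enrichment.tsv`` and ``expressed_counts.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for cond, partitions in bundle.partitions.items():
        for part in partitions:
            for mod in part.modules:
                for gene in sorted(mod.proteins):
                    rows.append((cond, part.stage, mod.id, gene))
    p = directory / "modules.tsv"
    _write_tsv(pd.DataFrame(rows, columns=["condition", "stage", "module_id", "gene"]), p)
    written.append(p)

    rows = []
    for cond, lineages in bundle.lineages.items():
        for i, lin in enumerate(lineages, start=1):
            chain = ";".join(f"{stage}:{mid}" for stage, mid in lin.chain)
            cn = ";".join(_FLOAT_FMT % m.c_n for m in lin.transitions)
            cl = ";".join(_FLOAT_FMT % m.c_l for m in lin.transitions)
            cgo = ";".join(_FLOAT_FMT % m.c_go for m in lin.transitions)
            rows.append((cond, f"{cond}-L{i}", lin.status, lin.size, chain, cn, cl, cgo))
    p = directory / "lineages.tsv"
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "condition", "lineage_id", "status", "size",
                "chain", "C_N", "C_L", "C_GO",
            ],
        ),
        p,
    )
    written.append(p)

    rows = []
    for call in bundle.disruption_calls:
        rows.append(
            (call.lineage_id, *["T" if b else "F" for b in call.correspondence], call.type)
        )
    ncols = max((len(c.correspondence) for c in bundle.disruption_calls), default=4)
    p = directory / "disruption_calls.tsv"
    _write_tsv(
        pd.DataFrame(
            rows, columns=["lineage_id"] + [f"b{i+1}" for i in range(ncols)] + ["type"]
        ),
        p,
    )
    written.append(p)

    rows = []
    for cond, summaries in bundle.null_summaries.items():
        for kind, ns in summaries.items():
            rows.append((cond, kind, ns.observed, ns.null_mean, ns.null_sd, ns.z))
    p = directory / "delta_ratios.tsv"
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["condition", "ratio_type", "observed", "null_mean", "null_sd", "z"],
        ),
        p,
    )
    written.append(p)

    rows = []
    for cond, per_stage in bundle.enrichment.items():
        for stage, results in per_stage.items():
            for r in results:
                rows.append(
                    (cond, stage, r.module_id, r.term, r.x, r.m, r.n, r.N,
                     r.p, r.fer, r.assigned)
                )
    p = directory / "enrichment.tsv"
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["condition", "stage", "module_id", "go_id",
                     "x", "m", "n", "N", "p", "FER", "assigned"],
        ),
        p,
    )
    written.append(p)

    rows = []
    for cond, per_stage in bundle.expressed_counts.items():
        for stage, (n_expr, n_nodes, n_edges) in per_stage.items():
            rows.append((cond, stage, n_expr, n_nodes, n_edges))
    p = directory / "expressed_counts.tsv"
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["condition", "stage", "expressed_proteins",
                     "pin_proteins", "pin_interactions"],
        ),
        p,
    )
    written.append(p)
    return written
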