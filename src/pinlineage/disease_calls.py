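"""Cross-condition module correspondence and disruption typing.

The two conditions (normal aging, disease progression) are aligned
stage-by-stage in order — e.g. the 60-69 y/o group with the earliest
Braak stage, and so on.  At each aligned stage pair, an aging module
corresponds to a disease module when the pair is mutual-best by C_L with
both C_L and C_GO strictly above 0.5 (the same machinery as
within-condition tracking, applied across conditions at one stage).

Each *inherited* aging lineage then receives a correspondence flag per
aligned stage and is typed from the flag vector (b1..bT):

* late-disrupted: corresponds early (b1) but not at the final stage (¬bT)
  — the module survives normal aging yet collapses late in disease;
* early-disrupted: no early correspondence (¬b1) but some later one
  — the module is absent early in disease yet recognizable later;
* other: anything else (including uninterrupted correspondence).

Intermediate-gap patterns such as (T,F,T,T) deliberately fall into
"other": only the two endpoint-anchored types have a defined reading.
"""

from __future__ import annotations

from dataclasses import dataclass

from .community import ModulePartition
from .errors import ConfigurationError, InputError
from .io_formats import AnnotationMap
from .tracking import Lineage, TrackingConfig, mutual_best_pairs


@dataclass(frozen=True)
class StageAlignment:
    pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class DisruptionCall:
    lineage_id: str
    correspondence: tuple[bool, ...]
    type: str  # early_disrupted | late_disrupted | other


def align_stages(aging_series, disease_series) -> StageAlignment:
    """Positionally pair two equal-length ordered stage series."""
    aging = list(aging_series)
    disease = list(disease_series)
    if len(aging) != len(disease):
        raise ConfigurationError(
            f"stage series lengths differ: {len(aging)} vs {len(disease)}"
        )
    return StageAlignment(tuple(zip(aging, disease)))


def cross_condition_correspondence(
    aging_partition: ModulePartition,
    disease_partition: ModulePartition,
    annotations: AnnotationMap,
    config: TrackingConfig | None = None,
) -> dict[int, bool]:
    """Per aging-module correspondence flags at one aligned stage pair.

    A module corresponds iff it sits in a mutual-best C_L pair with a
    disease module and both C_L and C_GO strictly exceed the thresholds.
    """
    config = config or TrackingConfig()
    flags = {mod.id: False for mod in aging_partition.modules}
    for m in mutual_best_pairs(aging_partition, disease_partition, annotations, config):
        if m.c_l > config.cl_threshold and m.c_go > config.cgo_threshold:
            flags[m.module_t.id] = True
    return flags


def classify_lineage(aging_lineage: Lineage, correspondence_vector) -> DisruptionCall:
    """Type an inherited aging lineage from its per-stage correspondence flags."""
    if aging_lineage.status != "inherited":
        raise InputError(
            "only inherited aging lineages are classified; got status "
            f"{aging_lineage.status!r}"
        )
    b = tuple(bool(x) for x in correspondence_vector)
    if len(b) != len(aging_lineage.chain):
        raise InputError(
            f"correspondence vector length {len(b)} does not match the "
            f"lineage's {len(aging_lineage.chain)} stages"
        )
    if b[0] and not b[-1]:
        kind = "late_disrupted"
    elif not b[0] and any(b[1:]):
        kind = "early_disrupted"
    else:
        kind = "other"
    lineage_id = "L" + "-".join(str(mid) for _, mid in aging_lineage.chain)
    return DisruptionCall(lineage_id, b, kind)


def disruption_table(calls) -> dict:
    """Counts and ratios of disruption types over inherited aging lineages."""
    calls = list(calls)
    total = len(calls)
    out = {"total": total, "counts": {}, "ratios": {}}
    for kind in ("early_disrupted", "late_disrupted", "other"):
        n = sum(1 for c in calls if c.type == kind)
        out["counts"][kind] = n
        out["ratios"][kind] = n / total if total else 0.0
    return out


def call_disruptions(
    aging_lineages,
    aging_partitions,
    disease_partitions,
    annotations: AnnotationMap,
    config: TrackingConfig | None = None,
) -> list[DisruptionCall]:
    """Classify every inherited aging lineage against the disease series.

    Correspondence is evaluated per aligned stage independently using the
    lineage's own module at that stage.
    """
    config = config or TrackingConfig()
    aging_partitions = list(aging_partitions)
    disease_partitions = list(disease_partitions)
    if len(aging_partitions) != len(disease_partitions):
        raise ConfigurationError("conditions have different stage counts")
    flags_per_stage = [
        cross_condition_correspondence(a, d, annotations, config)
        for a, d in zip(aging_partitions, disease_partitions)
    ]
    calls = []
    for lin in aging_lineages:
        if lin.status != "inherited":
            continue
        vec = [flags_per_stage[t].get(mid, False) for t, mid in lin.chain]
        calls.append(classify_lineage(lin, vec))
    return calls
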