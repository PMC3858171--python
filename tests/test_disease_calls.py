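import pytest

from pinlineage.community import Module, ModulePartition
from pinlineage.disease_calls import (
    align_stages,
    call_disruptions,
    classify_lineage,
    cross_condition_correspondence,
    disruption_table,
)
from pinlineage.errors import ConfigurationError, InputError
from pinlineage.tracking import Lineage


def module(mid, *proteins, edges=()):
    return Module(mid, frozenset(proteins), frozenset(tuple(sorted(e)) for e in edges))


def inherited_lineage(n_stages=4):
    return Lineage(
        chain=tuple((t, 1) for t in range(n_stages)),
        status="inherited",
        transitions=(),
        proteins=frozenset({"a", "b", "c"}),
    )


class TestAlignStages:
    def test_positional_pairing(self):
        al = align_stages(["60-69", "70-79", "80-89", "90-99"],
                          ["BraakI", "BraakII", "BraakIII", "BraakIV"])
        assert al.pairs[0] == ("60-69", "BraakI")
        assert al.pairs[-1] == ("90-99", "BraakIV")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            align_stages(["1", "2", "3"], ["1", "2", "3", "4"])

    def test_identity_alignment(self):
        al = align_stages(["1", "2"], ["1", "2"])
        assert al.pairs == (("1", "1"), ("2", "2"))


class TestCorrespondence:
    def test_identical_partitions_all_correspond(self):
        m1 = module(1, "a", "b", "c", edges=[("a", "b"), ("b", "c")])
        m2 = module(2, "x", "y", "z", edges=[("x", "y"), ("y", "z")])
        part = ModulePartition("1", (m1, m2))
        flags = cross_condition_correspondence(part, part, {})
        assert flags == {1: True, 2: True}

    def test_missing_disease_module_gives_no_correspondence(self):
        m1 = module(1, "a", "b", "c", edges=[("a", "b"), ("b", "c")])
        m2 = module(2, "x", "y", "z", edges=[("x", "y"), ("y", "z")])
        aging = ModulePartition("1", (m1, m2))
        disease = ModulePartition("1", (module(1, "a", "b", "c",
                                               edges=[("a", "b"), ("b", "c")]),))
        flags = cross_condition_correspondence(aging, disease, {})
        assert flags == {1: True, 2: False}

    def test_exactly_half_cl_is_not_correspondence(self):
        a = module(1, "a", "b", "c",
                   edges=[("a", "b"), ("b", "c"), ("a", "c")])
        d = module(1, "a", "b", "c", "d",
                   edges=[("a", "b"), ("b", "c"), ("a", "c"),
                          ("c", "d"), ("b", "d"), ("a", "d")])
        flags = cross_condition_correspondence(
            ModulePartition("1", (a,)), ModulePartition("1", (d,)), {}
        )
        assert flags == {1: False}


class TestClassify:
    @pytest.mark.parametrize(
        "vector,expected",
        [
            ((True, True, True, False), "late_disrupted"),
            ((True, False, False, False), "late_disrupted"),
            ((False, True, True, True), "early_disrupted"),
            ((False, False, False, True), "early_disrupted"),
            ((True, True, True, True), "other"),
            ((False, False, False, False), "other"),
            ((True, False, True, True), "other"),
        ],
    )
    def test_endpoint_anchored_typing(self, vector, expected):
        call = classify_lineage(inherited_lineage(), vector)
        assert call.type == expected
        assert call.correspondence == vector

    def test_non_inherited_lineage_rejected(self):
        lin = Lineage(((1, 1), (2, 1)), "appearing", (), frozenset({"a"}))
        with pytest.raises(InputError):
            classify_lineage(lin, (True, True))

    def test_vector_length_must_match_chain(self):
        with pytest.raises(InputError):
            classify_lineage(inherited_lineage(4), (True, True))


class TestDisruptionTable:
    def test_hand_ratio(self):
        calls = [
            classify_lineage(inherited_lineage(), v)
            for v in [
                (True, True, True, False),
                (True, True, True, False),
                (True, True, True, True),
                (True, True, True, True),
                (True, True, True, True),
            ]
        ]
        table = disruption_table(calls)
        assert table["counts"]["late_disrupted"] == 2
        assert table["ratios"]["late_disrupted"] == pytest.approx(0.4)
        assert sum(table["counts"].values()) == table["total"]

    def test_empty_calls(self):
        table = disruption_table([])
        assert table["total"] == 0
        assert all(v == 0 for v in table["counts"].values())


class TestEndToEnd:
    def test_counts_sum_to_inherited_lineages(self, mini_bundle):
        n_inherited = sum(
            1 for l in mini_bundle.lineages["stable"] if l.status == "inherited"
        )
        assert mini_bundle.disruption_summary["total"] == n_inherited
        assert sum(mini_bundle.disruption_summary["counts"].values()) == n_inherited

    def test_planted_late_silenced_modules_called_late(self, mini_truth, mini_bundle):
        def jac(a, b):
            return len(a & b) / len(a | b)

        calls = {c.lineage_id: c for c in mini_bundle.disruption_calls}
        inh = [l for l in mini_bundle.lineages["stable"] if l.status == "inherited"]
        hits = 0
        for j in mini_truth.config.disrupted_module_ids:
            members = mini_truth.planted_modules[j]
            best = max(inh, key=lambda l: jac(members, l.proteins))
            lid = "L" + "-".join(str(m) for _, m in best.chain)
            if jac(members, best.proteins) > 0.5 and calls[lid].type == "late_disrupted":
                hits += 1
        assert hits == len(mini_truth.config.disrupted_module_ids)

    def test_early_silenced_restored_module_called_early(self):
        from dataclasses import replace

        from pinlineage.pipeline import AnalysisParams, analyze
        from pinlineage.synthetic_data import (
            generate_stage_series,
            generate_truth,
        )
        from tests.conftest import MINI

        cfg = replace(MINI, disruption_schedule=(1.0, 0.0, 0.0, 0.0))
        truth = generate_truth(cfg)
        datasets = {
            c: generate_stage_series(truth, c) for c in ("stable", "disease")
        }
        bundle = analyze(
            truth.interactions,
            datasets,
            truth.annotations,
            AnalysisParams(trials=10, null_reps=60, seed=11),
        )

        def jac(a, b):
            return len(a & b) / len(a | b)

        calls = {c.lineage_id: c for c in bundle.disruption_calls}
        inh = [l for l in bundle.lineages["stable"] if l.status == "inherited"]
        hits = 0
        for j in cfg.disrupted_module_ids:
            members = truth.planted_modules[j]
            best = max(inh, key=lambda l: jac(members, l.proteins))
            lid = "L" + "-".join(str(m) for _, m in best.chain)
            if jac(members, best.proteins) > 0.5 and calls[lid].type == "early_disrupted":
                hits += 1
        assert hits == len(cfg.disrupted_module_ids)

    def test_condition_stage_count_mismatch_rejected(self, mini_bundle):
        with pytest.raises(ConfigurationError):
            call_disruptions(
                mini_bundle.lineages["stable"],
                mini_bundle.partitions["stable"],
                mini_bundle.partitions["disease"][:3],
                {},
            )
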