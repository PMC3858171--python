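import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinlineage.community import Module, ModulePartition
from pinlineage.errors import InputError
from pinlineage.tracking import (
    TrackingConfig,
    autocorrelation,
    build_lineages,
    lineage_summary,
    module_feature_sets,
    mutual_best_pairs,
)


def module(mid, *proteins, edges=()):
    return Module(
        mid,
        frozenset(proteins),
        frozenset(tuple(sorted(e)) for e in edges),
    )


def partition(stage, *modules):
    return ModulePartition(stage, tuple(modules))


class TestAutocorrelation:
    def test_hand_examples(self):
        assert autocorrelation({"a"}, {"a"}) == 1.0
        assert autocorrelation({"a"}, {"b"}) == 0.0
        assert autocorrelation({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_convention(self):
        assert autocorrelation(set(), set()) == 1.0
        assert autocorrelation({"a"}, set()) == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.frozensets(st.integers(0, 12), max_size=8),
        b=st.frozensets(st.integers(0, 12), max_size=8),
    )
    def test_symmetry_range_identity(self, a, b):
        j = autocorrelation(a, b)
        assert j == autocorrelation(b, a)
        assert 0.0 <= j <= 1.0
        if a or b:
            assert (j == 1.0) == (a == b)


class TestFeatureSets:
    def test_go_set_is_union_of_member_terms(self):
        m = module(1, "A", "B", "C", edges=[("A", "B")])
        ann = {"A": frozenset({"g1"}), "B": frozenset({"g1", "g2"})}
        prots, edges, go = module_feature_sets(m, ann)
        assert prots == {"A", "B", "C"}
        assert edges == {("A", "B")}
        assert go == {"g1", "g2"}

    def test_unannotated_members_give_empty_go_set(self):
        _, _, go = module_feature_sets(module(1, "X", "Y"), {})
        assert go == frozenset()


class TestMutualBest:
    def test_identical_single_modules_inherit(self):
        m = module(1, "A", "B", "C", edges=[("A", "B"), ("B", "C")])
        pairs = mutual_best_pairs(partition(0, m), partition(1, m), {})
        assert len(pairs) == 1
        p = pairs[0]
        assert p.c_n == p.c_l == 1.0 and p.c_go == 1.0 and p.inherited

    def test_non_mutual_best_is_unpaired(self):
        # X's best is Y (its only option), but Y's best is Z: X stays unpaired
        x = module(1, "a", "b", "c", edges=[("a", "b"), ("b", "c")])
        z = module(2, "d", "e", "f", "g", edges=[("d", "e"), ("e", "f"), ("f", "g")])
        y = module(1, "a", "b", "d", "e", "f",
                   edges=[("a", "b"), ("d", "e"), ("e", "f")])
        # C_L(X,Y) = 1/4 < C_L(Z,Y) = 2/4
        pairs = mutual_best_pairs(partition(0, x, z), partition(1, y), {})
        assert [(p.module_t.id, p.module_t1.id) for p in pairs] == [(2, 1)]

    def test_two_vs_three_toy_verified_by_enumeration(self):
        red = module(1, "a", "b", "c", edges=[("a", "b"), ("b", "c")])
        blue = module(2, "x", "y", "z", edges=[("x", "y"), ("y", "z")])
        green = module(1, "a", "b", "c", edges=[("a", "b"), ("b", "c")])
        purple = module(2, "x", "y", "w", edges=[("x", "y")])
        grey = module(3, "p", "q", "r", edges=[("p", "q")])
        p_t = partition(0, red, blue)
        p_t1 = partition(1, green, purple, grey)
        # brute-force all 6 cross pairs
        def cl(m1, m2):
            return autocorrelation(m1.edges, m2.edges)

        best_fwd = {
            m1.id: max(p_t1.modules, key=lambda m2: cl(m1, m2)).id
            for m1 in p_t.modules
        }
        best_bwd = {
            m2.id: max(p_t.modules, key=lambda m1: cl(m1, m2)).id
            for m2 in p_t1.modules
        }
        expected = {
            (a, b)
            for a, b in best_fwd.items()
            if best_bwd[b] == a
        }
        pairs = mutual_best_pairs(p_t, p_t1, {})
        assert {(p.module_t.id, p.module_t1.id) for p in pairs} == expected
        for p in pairs:
            assert p.c_l == cl(p.module_t, p.module_t1)

    def test_strict_threshold_at_exactly_half(self):
        # C_L exactly 0.5 must not be inherited ("exceeded 0.5" is strict)
        a2 = module(1, "a", "b", "c",
                    edges=[("a", "b"), ("b", "c"), ("a", "c")])
        b2 = module(1, "a", "b", "c", "d",
                    edges=[("a", "b"), ("b", "c"), ("a", "c"),
                           ("c", "d"), ("b", "d"), ("a", "d")])
        # intersection 3, union 6 -> exactly 0.5
        pairs = mutual_best_pairs(partition(0, a2), partition(1, b2), {})
        assert len(pairs) == 1 and pairs[0].c_l == 0.5
        assert not pairs[0].inherited


class TestLineages:
    def _chain_partitions(self, spans):
        """Build 4-stage partitions where each span (start, stop) is a module
        chain kept identical (hence inherited) across its stages."""
        mods_per_stage = [[] for _ in range(4)]
        for k, (start, stop) in enumerate(spans):
            letters = [chr(ord("a") + 3 * k + i) for i in range(3)]
            edges = [(letters[0], letters[1]), (letters[1], letters[2])]
            for t in range(start, stop + 1):
                mods_per_stage[t].append((k, letters, edges))
        partitions = []
        for t, specs in enumerate(mods_per_stage):
            mods = tuple(
                Module(i + 1, frozenset(l), frozenset(tuple(sorted(e)) for e in ed))
                for i, (_, l, ed) in enumerate(specs)
            )
            partitions.append(ModulePartition(str(t + 1), mods))
        return partitions

    @pytest.mark.parametrize(
        "span,status",
        [
            ((0, 3), "inherited"),
            ((0, 2), "disrupted"),
            ((1, 3), "appearing"),
            ((1, 2), "disappearing"),
        ],
    )
    def test_status_from_span(self, span, status):
        parts = self._chain_partitions([span])
        lineages = build_lineages(parts, {})
        assert [l.status for l in lineages] == [status]
        assert lineages[0].chain[0][0] == span[0]
        assert lineages[0].chain[-1][0] == span[1]

    def test_every_module_in_exactly_one_lineage(self, mini_bundle):
        for cond in ("stable", "disease"):
            lineages = mini_bundle.lineages[cond]
            partitions = mini_bundle.partitions[cond]
            assert sum(len(l.chain) for l in lineages) == sum(
                len(p.modules) for p in partitions
            )
            seen = set()
            for l in lineages:
                for link in l.chain:
                    assert link not in seen
                    seen.add(link)

    def test_threshold_monotonicity(self, mini_bundle, mini_truth):
        parts = mini_bundle.partitions["stable"]
        counts = []
        for thr in (0.3, 0.4, 0.5, 0.6, 0.7):
            lins = build_lineages(
                parts, mini_truth.annotations, TrackingConfig(thr, thr)
            )
            counts.append(sum(1 for l in lins if l.status == "inherited"))
        assert counts == sorted(counts, reverse=True)

    def test_single_partition_rejected(self):
        with pytest.raises(InputError):
            build_lineages([ModulePartition("1", ())], {})


class TestLineageSummary:
    def test_all_inherited_ratio_one(self):
        parts = TestLineages()._chain_partitions([(0, 3), (0, 3)])
        lins = build_lineages(parts, {})
        s = lineage_summary(lins)
        assert s["ratios"]["inherited"] == 1.0

    def test_hand_ratio(self):
        parts = TestLineages()._chain_partitions(
            [(0, 3), (0, 3), (0, 3)] + [(1, 3)] * 9
        )
        s = lineage_summary(build_lineages(parts, {}))
        assert s["total"] == 12
        assert s["ratios"]["inherited"] == 0.25

    def test_empty_summary(self):
        assert lineage_summary([])["total"] == 0
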