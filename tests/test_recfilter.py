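import numpy as np
import pytest

from recessmap.core import GeneModel, Variant, VariantCallSet
from recessmap.datasets import candidate_variants, panel_callset
from recessmap.recfilter import (classify_variant_region,
                                 cross_population_exclusion,
                                 recessive_compatibility_filter)


def make_calls(rows, samples=("CASE", "CARRIER", "C1", "C2")):
    """rows: list of (pos, ref, alt, gts-per-sample)."""
    variants = [Variant("3", pos, ref, alt, f"v{i}",
                        np.array(gts, dtype=np.int8))
                for i, (pos, ref, alt, gts) in enumerate(rows)]
    return VariantCallSet(list(samples), variants)


GOOD = [(1, 1), (0, 1), (0, 0), (0, 0)]


class TestCompatibilityFilter:
    def filter(self, calls, **kw):
        return recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                              ["C1", "C2"], **kw)

    def test_single_compatible_of_three(self):
        calls = make_calls([
            (100, "A", "T", GOOD),
            (200, "G", "C", [(0, 1), (0, 1), (0, 0), (0, 0)]),   # case het
            (300, "T", "A", [(1, 1), (0, 1), (0, 1), (0, 0)]),   # control carries
        ])
        cands = self.filter(calls)
        assert [c.variant.pos for c in cands] == [100]
        assert cands[0].compatible

    def test_control_het_excluded(self):
        calls = make_calls([(100, "A", "T",
                             [(1, 1), (0, 1), (0, 0), (0, 1)])])
        assert self.filter(calls) == []

    def test_carrier_hom_alt_excluded(self):
        calls = make_calls([(100, "A", "T",
                             [(1, 1), (1, 1), (0, 0), (0, 0)])])
        assert self.filter(calls) == []

    def test_missing_strict_vs_lenient(self):
        calls = make_calls([(100, "A", "T",
                             [(1, 1), (0, 1), (-1, -1), (0, 0)])])
        assert self.filter(calls) == []
        assert len(self.filter(calls, strict_missing=False)) == 1

    def test_lenient_all_missing_group_fails(self):
        calls = make_calls([(100, "A", "T",
                             [(1, 1), (-1, -1), (0, 0), (0, 0)])])
        assert self.filter(calls, strict_missing=False) == []

    def test_empty_group_raises(self):
        calls = make_calls([(100, "A", "T", GOOD)])
        with pytest.raises(ValueError, match="empty control"):
            recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"], [])

    def test_sample_order_invariance(self):
        calls = make_calls([(100, "A", "T", GOOD)])
        a = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                           ["C1", "C2"])
        b = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                           ["C2", "C1"])
        assert [c.key for c in a] == [c.key for c in b]

    def test_adding_control_only_shrinks(self):
        rows = [(100, "A", "T", GOOD + [(0, 0)]),
                (200, "G", "C", GOOD + [(0, 1)])]
        calls = make_calls(rows, samples=("CASE", "CARRIER", "C1", "C2", "C3"))
        small = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                               ["C1", "C2"])
        big = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                             ["C1", "C2", "C3"])
        assert {c.key for c in big} <= {c.key for c in small}

    def test_indel_normalization(self):
        # CCC->CC at pos 100 normalizes to the anchored 1-bp deletion
        calls = make_calls([(100, "CCC", "CC", GOOD)])
        cand = self.filter(calls)[0]
        assert (cand.variant.pos, cand.variant.ref, cand.variant.alt) == \
            (100, "CC", "C")


class TestCrossPopulationExclusion:
    def test_published_candidates_retain_two(self):
        retained, excluded = cross_population_exclusion(candidate_variants(),
                                                        panel_callset())
        assert len(retained) == 2 and len(excluded) == 8
        assert {c.variant.vid for c in retained} == \
            {"rs723240647", "rs715250609"}

    def test_empty_panel_retains_all(self):
        cands = candidate_variants()
        retained, excluded = cross_population_exclusion(cands, None)
        assert len(retained) == len(cands) and excluded == []
        assert all(c.panel_polymorphic is None for c in retained)

    def test_fully_polymorphic_panel_excludes_all(self):
        calls = make_calls([(100, "A", "T", GOOD)])
        cands = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                               ["C1", "C2"])
        panel = make_calls([(100, "A", "T",
                             [(0, 1), (0, 0), (0, 0), (0, 0)])],
                           samples=("P1", "P2", "P3", "P4"))
        retained, excluded = cross_population_exclusion(cands, panel)
        assert retained == [] and len(excluded) == 1

    def test_untested_candidate_annotated(self):
        calls = make_calls([(100, "A", "T", GOOD)])
        cands = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                               ["C1", "C2"])
        panel = make_calls([(999, "G", "A", [(0, 0)] * 4)],
                           samples=("P1", "P2", "P3", "P4"))
        retained, _ = cross_population_exclusion(cands, panel)
        assert retained[0].panel_polymorphic is None

    def test_monomorphic_panel_record_retains(self):
        calls = make_calls([(100, "A", "T", GOOD)])
        cands = recessive_compatibility_filter(calls, ["CASE"], ["CARRIER"],
                                               ["C1", "C2"])
        panel = make_calls([(100, "A", "T", [(0, 0)] * 4)],
                           samples=("P1", "P2", "P3", "P4"))
        retained, _ = cross_population_exclusion(cands, panel)
        assert len(retained) == 1
        assert retained[0].panel_polymorphic is False


class TestClassifyRegion:
    def variant(self, pos, ref="A", alt="T"):
        return Variant("3", pos, ref, alt, ".", np.zeros((0, 2), np.int8))

    def test_region_classes_on_fixture(self, default_fixture):
        gene = default_fixture.gene
        exon1 = gene.exons[0]
        c = classify_variant_region(self.variant(exon1[0]), gene)
        assert c.region == "exonic" and c.splice_distance is None

        c = classify_variant_region(self.variant(exon1[1] + 1), gene)
        assert c.region == "intronic" and c.splice_distance == 1
        assert c.priority == "candidate"

        c = classify_variant_region(self.variant(gene.span[0] - 100), gene)
        assert c.region == "intergenic"

    def test_deep_intronic_deprioritized(self, default_fixture):
        gene = default_fixture.gene
        li = default_fixture.spec.long_intron_index
        intron_start = gene.exons[li - 1][1] + 1
        c = classify_variant_region(self.variant(intron_start + 4499), gene)
        assert c.region == "intronic"
        assert c.splice_distance == 4500
        assert c.priority == "deprioritized"

    def test_threshold_configurable(self, default_fixture):
        gene = default_fixture.gene
        li = default_fixture.spec.long_intron_index
        intron_start = gene.exons[li - 1][1] + 1
        c = classify_variant_region(self.variant(intron_start + 4499), gene,
                                    splice_distance_threshold=5000)
        assert c.priority == "candidate"

    def test_positions_partition_the_gene(self, default_fixture):
        gene = default_fixture.gene
        rng = np.random.default_rng(0)
        lo, hi = gene.span
        for pos in rng.integers(lo - 50, hi + 50, size=200):
            c = classify_variant_region(self.variant(int(pos)), gene)
            assert c.region in ("exonic", "intronic", "intergenic")

    def test_malformed_gene_model_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("g", "t", "3", "+", [(1, 100), (50, 200)])
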