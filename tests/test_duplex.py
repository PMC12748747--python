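import random
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

import duplexrepair as dr
from duplexrepair.duplex import (
    AMBIGUOUS,
    DuplexCall,
    FilterParams,
    UmiFamily,
    family_read_threshold,
    reconstruct_molecules,
)
from duplexrepair.readproc import AnnotatedRead

from oracle_utils import nested_loop_group


def ar(umi, strand, label="direct", read_id=None, sample="s1"):
    return AnnotatedRead(read_id or f"{umi}-{strand}-{random.random()}",
                         sample, umi, strand, label, 0)


def family(umi, n_top=0, n_bottom=0, top_label="direct", bottom_label="direct"):
    return UmiFamily(
        umi,
        reads_top=[ar(umi, "top", top_label, f"{umi}t{i}") for i in range(n_top)],
        reads_bottom=[ar(umi, "bottom", bottom_label, f"{umi}b{i}")
                      for i in range(n_bottom)],
    )


class TestGrouping:
    def test_two_reads_same_umi_one_family(self):
        fams = dr.group_by_umi([ar("AAAAAAAAAA", "top"), ar("AAAAAAAAAA", "bottom")])
        assert len(fams) == 1
        assert fams[0].n_top == 1 and fams[0].n_bottom == 1

    def test_one_mismatch_umis_stay_separate(self):
        fams = dr.group_by_umi([ar("AAAAAAAAAA", "top"), ar("AAAAAAAAAT", "top")])
        assert len(fams) == 2

    def test_undetermined_strand_excluded(self):
        fams = dr.group_by_umi([ar("AAAAAAAAAA", "top"),
                                ar("AAAAAAAAAA", "undetermined")])
        assert len(fams) == 1
        assert fams[0].n_reads == 1

    def test_grouping_matches_nested_loop_oracle(self, gt5, gt5_products,
                                                 small_error_free_library):
        _, records, _ = small_error_free_library
        subset = records[:1000]
        annotated, _ = dr.annotate_reads(subset, gt5, gt5_products,
                                         {"s1": "ACGTAC"})
        fams = {f.umi: f for f in dr.group_by_umi(annotated)}
        oracle = nested_loop_group(annotated)
        assert set(fams) == set(oracle)
        for umi, sides in oracle.items():
            assert fams[umi].n_top == len(sides["top"])
            assert fams[umi].n_bottom == len(sides["bottom"])


class TestFamilyFilter:
    PARAMS = FilterParams(n_input_templates=10)

    def test_threshold_arithmetic(self):
        # 2000 reads over 10 templates: threshold = 0.02 * 200 = 4 reads
        assert family_read_threshold(2000, self.PARAMS) == pytest.approx(4.0)

    def test_family_below_threshold_dropped(self):
        fams = [family("A" * 10, n_top=3)]
        assert dr.filter_families(fams, 2000, self.PARAMS) == []

    def test_family_at_threshold_retained(self):
        # strict "less than": exactly 4 reads survives
        fams = [family("A" * 10, n_top=4)]
        assert len(dr.filter_families(fams, 2000, self.PARAMS)) == 1

    def test_shallow_oversampling_keeps_all_nonempty_families(self):
        fams = [family("A" * 10, n_top=1), family("C" * 10, n_bottom=1)]
        params = FilterParams(n_input_templates=100)
        assert family_read_threshold(100, params) < 1
        assert len(dr.filter_families(fams, 100, params)) == 2

    def test_total_reads_smaller_than_grouped_raises(self):
        with pytest.raises(ValueError):
            dr.filter_families([family("A" * 10, n_top=5)], 3, self.PARAMS)

    def test_order_independent(self):
        fams = [family(f"{i:010d}".replace("1", "A").replace("0", "C"),
                       n_top=i % 7) for i in range(1, 30)]
        fams = [f for f in fams if f.n_reads]
        kept_fwd = {f.umi for f in dr.filter_families(fams, 5000, self.PARAMS)}
        kept_rev = {f.umi for f in dr.filter_families(fams[::-1], 5000,
                                                      self.PARAMS)}
        assert kept_fwd == kept_rev


class TestStrandFilter:
    PARAMS = FilterParams(n_input_templates=10)

    def test_minor_strand_dropped(self):
        out = dr.filter_strands(family("A" * 10, n_top=9, n_bottom=1), self.PARAMS)
        assert out.n_top == 9 and out.n_bottom == 0

    def test_exactly_twenty_percent_retained(self):
        out = dr.filter_strands(family("A" * 10, n_top=8, n_bottom=2), self.PARAMS)
        assert out.n_top == 8 and out.n_bottom == 2

    def test_single_strand_family_unchanged(self):
        out = dr.filter_strands(family("A" * 10, n_top=5), self.PARAMS)
        assert out.n_top == 5 and out.n_bottom == 0

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_never_drops_both_strands(self, n_top, n_bottom):
        if n_top + n_bottom == 0:
            return
        out = dr.filter_strands(family("A" * 10, n_top=n_top, n_bottom=n_bottom),
                                FilterParams(n_input_templates=10))
        assert out.n_reads > 0
        assert out.n_top == n_top or out.n_bottom == n_bottom


class TestConsensus:
    def test_unanimous(self):
        fam = dr.call_consensus(family("A" * 10, n_top=5, top_label="ins:C"))
        assert fam.consensus_top == "ins:C"
        assert fam.consensus_bottom is None

    def test_tie_is_ambiguous(self):
        fam = family("A" * 10)
        fam.reads_top = [ar("A" * 10, "top", "direct", f"d{i}") for i in range(2)]
        fam.reads_top += [ar("A" * 10, "top", "ins:C", f"c{i}") for i in range(2)]
        assert dr.call_consensus(fam).consensus_top == AMBIGUOUS

    def test_plurality_beats_unclassified(self):
        fam = family("A" * 10)
        fam.reads_top = [ar("A" * 10, "top", "direct", f"d{i}") for i in range(3)]
        fam.reads_top.append(ar("A" * 10, "top", "unclassified", "u0"))
        # counting oracle
        from collections import Counter

        counts = Counter(r.label for r in fam.reads_top if r.label != "unclassified")
        assert counts.most_common(1)[0] == ("direct", 3)
        assert dr.call_consensus(fam).consensus_top == "direct"

    def test_only_unclassified_reads_is_ambiguous(self):
        fam = family("A" * 10)
        fam.reads_top = [ar("A" * 10, "top", "unclassified", f"u{i}")
                         for i in range(3)]
        assert dr.call_consensus(fam).consensus_top == AMBIGUOUS


class TestClassifyMolecule:
    def classify(self, products, top=None, bottom=None):
        fam = UmiFamily("A" * 10, consensus_top=top, consensus_bottom=bottom)
        if top:
            fam.reads_top = [ar("A" * 10, "top", top)]
        if bottom:
            fam.reads_bottom = [ar("A" * 10, "bottom", bottom)]
        return dr.classify_molecule(fam, products)

    def test_direct_direct_is_model1(self, gt5_products):
        call = self.classify(gt5_products, "direct", "direct")
        assert call.molecule_class == "both_joined"
        assert call.path == "model1"

    def test_model2_copy_pair_is_model2(self, gag3_products):
        call = self.classify(gag3_products, "ins:C", "model2_copy_of_ins:C")
        assert call.molecule_class == "both_joined"
        assert call.path == "model2"
        reverse = self.classify(gag3_products, "model2_copy_of_direct", "direct")
        assert reverse.path == "model2"

    def test_single_strand_calls(self, gt5_products):
        call = self.classify(gt5_products, top="direct")
        assert call.molecule_class == "top_only"
        assert call.path == "not_applicable"
        call = self.classify(gt5_products, bottom="direct")
        assert call.molecule_class == "bottom_only"

    def test_degenerate_joint_label_is_indeterminate(self, blunt_products):
        joint = "direct|model2_copy_of_direct"
        call = self.classify(blunt_products, joint, joint)
        assert call.molecule_class == "both_joined"
        assert call.path == "indeterminate"

    def test_mismatched_model2_sources_indeterminate(self, gag3_products):
        call = self.classify(gag3_products, "ins:C", "model2_copy_of_ins:TC")
        assert call.path == "indeterminate"

    def test_double_model2_indeterminate(self, gag3_products):
        call = self.classify(gag3_products, "model2_copy_of_ins:C",
                             "model2_copy_of_ins:C")
        assert call.path == "indeterminate"

    def test_ambiguous_consensus_gives_ambiguous_class(self, gt5_products):
        fam = UmiFamily("A" * 10, consensus_top=AMBIGUOUS,
                        consensus_bottom=AMBIGUOUS)
        call = dr.classify_molecule(fam, gt5_products)
        assert call.molecule_class == "ambiguous"
        assert call.path == "not_applicable"


def make_calls(n_model1=0, n_model2=0, n_indeterminate=0, n_top_only=0,
               n_bottom_only=0, n_ambiguous=0):
    calls = []

    def add(i, **kw):
        calls.append(DuplexCall(umi=f"{len(calls):010d}", **kw))

    for i in range(n_model1):
        add(i, top_label="direct", bottom_label="direct",
            molecule_class="both_joined", path="model1")
    for i in range(n_model2):
        add(i, top_label="ins:C", bottom_label="model2_copy_of_ins:C",
            molecule_class="both_joined", path="model2")
    for i in range(n_indeterminate):
        add(i, top_label="x|y", bottom_label="x|y",
            molecule_class="both_joined", path="indeterminate")
    for i in range(n_top_only):
        add(i, top_label="direct", bottom_label=None,
            molecule_class="top_only", path="not_applicable")
    for i in range(n_bottom_only):
        add(i, top_label=None, bottom_label="direct",
            molecule_class="bottom_only", path="not_applicable")
    for i in range(n_ambiguous):
        add(i, top_label=None, bottom_label=None,
            molecule_class="ambiguous", path="not_applicable")
    return calls


class TestSummaryAndRatio:
    def test_both_joined_frequency(self):
        summary = dr.summarize(make_calls(n_model1=72, n_top_only=18,
                                          n_bottom_only=10))
        assert summary.class_frequencies["both_joined"] == pytest.approx(0.72)

    def test_all_ambiguous(self):
        summary = dr.summarize(make_calls(n_ambiguous=5))
        assert summary.class_frequencies["ambiguous"] == 1.0
        assert sum(summary.class_frequencies.values()) == pytest.approx(1.0)

    def test_frequencies_match_counting_oracle(self, rng):
        calls = make_calls(
            n_model1=int(rng.integers(1, 40)),
            n_model2=int(rng.integers(1, 40)),
            n_indeterminate=int(rng.integers(0, 10)),
            n_top_only=int(rng.integers(0, 30)),
            n_ambiguous=int(rng.integers(0, 5)),
        )
        summary = dr.summarize(calls)
        for cls in ("both_joined", "top_only", "bottom_only", "ambiguous"):
            naive = sum(c.molecule_class == cls for c in calls) / len(calls)
            assert summary.class_frequencies[cls] == pytest.approx(naive)

    def test_exact_frequencies_sum_to_one(self):
        summary = dr.summarize(make_calls(n_model1=7, n_top_only=3,
                                          n_ambiguous=2))
        assert sum(summary.exact_class_frequencies().values()) == Fraction(1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            dr.summarize([])

    def test_preference_ratio_twenty_to_one(self):
        summary = dr.summarize(make_calls(n_model1=900, n_model2=45,
                                          n_indeterminate=55))
        ratio = dr.preference_ratio(summary)
        assert ratio.model1_to_model2 == pytest.approx(20.0)
        assert ratio.model2_to_model1 == pytest.approx(0.05)
        assert ratio.n_indeterminate == 55
        assert not ratio.zero_denominator

    def test_zero_denominator_flagged_not_raised(self):
        summary = dr.summarize(make_calls(n_model1=10))
        ratio = dr.preference_ratio(summary)
        assert ratio.zero_denominator
        assert ratio.model1_to_model2 == float("inf")
        assert ratio.n_model1 == 10

    def test_no_both_joined_raises(self):
        summary = dr.summarize(make_calls(n_top_only=5))
        with pytest.raises(ValueError):
            dr.preference_ratio(summary)


class TestReconstructEndToEnd:
    def test_error_free_library_matches_molecule_truth(
            self, gt5, gt5_products, small_error_free_library):
        states, records, _ = small_error_free_library
        annotated, stats = dr.annotate_reads(records, gt5, gt5_products,
                                             {"s1": "ACGTAC"})
        params = FilterParams(n_input_templates=len(states))
        calls, log = reconstruct_molecules(annotated, gt5_products, params,
                                           total_reads=stats.n_input)
        # ground truth class per molecule (dropping 0-read strands)
        truth_classes = {"both_joined": 0, "top_only": 0, "bottom_only": 0}
        for s in states:
            if s.top.joined and s.bottom.joined:
                truth_classes["both_joined"] += 1
            elif s.top.joined:
                truth_classes["top_only"] += 1
            elif s.bottom.joined:
                truth_classes["bottom_only"] += 1
        summary = dr.summarize(calls)
        # Poisson(12) can zero out a strand (~6e-6) and UMI collisions are
        # possible (~0.04 expected); allow a tolerance of 2 molecules.
        for cls, expected in truth_classes.items():
            assert abs(summary.class_counts[cls] - expected) <= 2
        assert summary.class_counts["ambiguous"] == 0
        assert log["family_read_threshold"] == pytest.approx(
            0.02 * stats.n_input / len(states)
        )

    def test_filters_are_deterministic_under_shuffling(self, rng):
        fams = []
        for i in range(40):
            umi = "".join("ACGT"[d] for d in rng.integers(0, 4, 10))
            fams.append(family(umi, n_top=int(rng.integers(0, 12)),
                               n_bottom=int(rng.integers(0, 12))))
        fams = [f for f in fams if f.n_reads]
        params = FilterParams(n_input_templates=20)
        total = 2000
        baseline = sorted(
            (f.umi, dr.filter_strands(f, params).n_top,
             dr.filter_strands(f, params).n_bottom)
            for f in dr.filter_families(fams, total, params)
        )
        shuffled = list(fams)
        random.Random(0).shuffle(shuffled)
        again = sorted(
            (f.umi, dr.filter_strands(f, params).n_top,
             dr.filter_strands(f, params).n_bottom)
            for f in dr.filter_families(shuffled, total, params)
        )
        assert baseline == again
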