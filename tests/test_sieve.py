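"""Candidate-sieve rules on hand-computed fixtures, plus grouping and classification."""

import pytest

from recinv import (
    ContigLayout,
    CrossoverInterval,
    SplitReadCandidate,
    TrioScaffoldAlignment,
    classify_groups,
    filter_by_length,
    filter_by_recombination,
    filter_by_trio_span,
    merge_groups,
    rescue_tentative,
    run_sieve,
)


def cand(start, end, species="cydno", sex="female", tier="default", chrom="chr1"):
    return SplitReadCandidate(chrom, start, end, species, sex, support_reads=3, support_tier=tier)


def xo(left, right, species="cydno", chrom="chr1"):
    return CrossoverInterval("o1", chrom, left, right, group_label=species)


def aln(start, end, orientation="forward", species="cydno", scaffold="s1", sex="female", chrom="chr1"):
    return TrioScaffoldAlignment(scaffold, species, sex, chrom, start, end, orientation)


class TestRecombinationFilter:
    def test_contained_same_species_crossover_rejects(self):
        kept, rejected = filter_by_recombination(
            [cand(100_000, 200_000)], [xo(120_000, 130_000)]
        )
        assert kept == [] and len(rejected) == 1

    def test_other_species_crossover_ignored(self):
        kept, _ = filter_by_recombination(
            [cand(100_000, 200_000)], [xo(120_000, 130_000, species="melpomene")]
        )
        assert len(kept) == 1

    def test_partial_overlap_is_not_containment(self):
        kept, _ = filter_by_recombination(
            [cand(100_000, 200_000)], [xo(90_000, 110_000)]
        )
        assert len(kept) == 1


class TestTrioSpanFilter:
    def test_spanning_forward_alignment_rejects(self):
        """10 kb candidate; forward alignment extends 6 kb (> L/2) both sides."""
        kept, rejected = filter_by_trio_span(
            [cand(100_000, 110_000)], [aln(94_000, 116_000)]
        )
        assert kept == [] and len(rejected) == 1

    def test_short_left_extension_keeps(self):
        kept, _ = filter_by_trio_span([cand(100_000, 110_000)], [aln(96_000, 116_000)])
        assert len(kept) == 1

    def test_reverse_alignment_never_rejects(self):
        kept, _ = filter_by_trio_span(
            [cand(100_000, 110_000)], [aln(90_000, 120_000, orientation="reverse")]
        )
        assert len(kept) == 1

    def test_other_species_scaffold_ignored(self):
        kept, _ = filter_by_trio_span(
            [cand(100_000, 110_000)], [aln(90_000, 120_000, species="melpomene")]
        )
        assert len(kept) == 1

    def test_either_mode_is_stricter(self):
        c = [cand(100_000, 110_000)]
        a = [aln(96_000, 116_000)]  # spans, long extension on the right only
        assert len(filter_by_trio_span(c, a, span_mode="both")[0]) == 1
        assert len(filter_by_trio_span(c, a, span_mode="either")[0]) == 0


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept",
        [(900, False), (1_000, True), (20_247, True)],
    )
    def test_strict_1kb_rule(self, length, kept):
        got_kept, got_rej = filter_by_length([cand(0, length)])
        assert (len(got_kept) == 1) is kept


class TestRescue:
    def test_overlapping_other_sample_rescued(self):
        t = cand(100, 200, sex="male", tier="tentative")
        d = cand(150, 300, sex="female")
        assert rescue_tentative([d], [t]) == [d, t]

    def test_isolated_tentative_dropped(self):
        t = cand(1_000_000, 1_000_100, tier="tentative")
        d = cand(150, 300)
        assert rescue_tentative([d], [t]) == [d]

    def test_same_sample_overlap_does_not_rescue(self):
        t = cand(100, 200, tier="tentative")
        d = cand(150, 300)  # same species and sex
        assert rescue_tentative([d], [t]) == [d]

    def test_no_tentative_identity(self):
        d = [cand(0, 1000)]
        assert rescue_tentative(d, []) == d


class TestMergeGroups:
    def test_two_components(self):
        groups = merge_groups([cand(1, 5), cand(4, 8), cand(10, 12)])
        assert [(g.start_bp, g.end_bp) for g in groups] == [(1, 8), (10, 12)]

    def test_transitive_chain(self):
        groups = merge_groups([cand(1, 5), cand(4, 8), cand(7, 12)])
        assert len(groups) == 1 and (groups[0].start_bp, groups[0].end_bp) == (1, 12)

    def test_empty(self):
        assert merge_groups([]) == []

    def test_abutting_half_open_intervals_do_not_merge(self):
        groups = merge_groups([cand(1, 5), cand(5, 9)])
        assert len(groups) == 2

    def test_groups_are_maximal(self):
        groups = merge_groups([cand(i * 3, i * 3 + 4) for i in range(20)])
        for g1 in groups:
            for g2 in groups:
                if g1 is not g2:
                    assert not (g1.start_bp < g2.end_bp and g2.start_bp < g1.end_bp)


class TestClassifyGroups:
    SPECIES = ("cydno", "melpomene")

    def test_split_and_trio(self):
        g = merge_groups([cand(100_000, 110_000, species="cydno")])
        alns = [
            aln(100_000, 110_000, "reverse", "cydno", "s1"),
            aln(90_000, 100_000, "forward", "cydno", "s1"),
        ]
        out = classify_groups(g, alns, all_species=self.SPECIES)
        assert out[0].classification == "split_and_trio"
        assert out[0].species_set == frozenset({"cydno"})

    def test_split_only_both_species(self):
        g = merge_groups(
            [cand(100_000, 110_000, species="cydno"), cand(105_000, 112_000, species="melpomene")]
        )
        out = classify_groups(g, [], all_species=self.SPECIES)
        assert out[0].classification == "split_only"
        assert out[0].species_set == frozenset(self.SPECIES)

    def test_split_one_trio_both(self):
        g = merge_groups([cand(100_000, 110_000, species="cydno")])
        alns = []
        for sp, scaf in (("cydno", "s1"), ("melpomene", "s2")):
            alns += [
                aln(100_000, 110_000, "reverse", sp, scaf),
                aln(90_000, 100_000, "forward", sp, scaf),
            ]
        out = classify_groups(g, alns, all_species=self.SPECIES)
        assert out[0].classification == "split_one_trio_both"
        assert out[0].species_set == frozenset(self.SPECIES)

    def test_near_contig_boundary_flag(self):
        g = merge_groups([cand(100_000, 110_000)])
        contigs = [ContigLayout("chr1", (98_000, 500_000))]
        out = classify_groups(g, [], contigs, near_bp=5_000, all_species=self.SPECIES)
        assert out[0].near_contig_boundary
        out = classify_groups(g, [], contigs, near_bp=1_000, all_species=self.SPECIES)
        assert not out[0].near_contig_boundary


class TestRunSieve:
    def test_filters_order_independent(self):
        """Each filter is a pure per-candidate predicate: the surviving set is
        the intersection of the filters however they are composed."""
        cands = [
            cand(100_000, 200_000),            # killed by recombination
            cand(300_000, 310_000),            # killed by trio span
            cand(500_000, 500_900),            # killed by length
            cand(700_000, 720_000),            # survives
        ]
        xs = [xo(120_000, 130_000)]
        alns = [aln(294_000, 316_000)]
        import itertools

        filters = {
            "rec": lambda cs: filter_by_recombination(cs, xs)[0],
            "trio": lambda cs: filter_by_trio_span(cs, alns)[0],
            "len": lambda cs: filter_by_length(cs)[0],
        }
        results = set()
        for order in itertools.permutations(filters):
            kept = list(cands)
            for name in order:
                kept = filters[name](kept)
            results.add(tuple(kept))
        assert results == {(cands[3],)}

    def test_report_reasons_partition_rejected(self):
        cands = [
            cand(100_000, 200_000),
            cand(300_000, 310_000),
            cand(500_000, 500_900),
            cand(700_000, 720_000),
            cand(900_000, 901_000, tier="tentative"),  # isolated tentative
        ]
        groups, report = run_sieve(
            cands, [xo(120_000, 130_000)], [aln(294_000, 316_000)]
        )
        rejected = report[report.decision == "rejected"]
        assert sorted(rejected.reason) == [
            "length",
            "recombination",
            "trio_span",
            "unrescued_tentative",
        ]
        assert len(groups) == 1
        assert (groups[0].start_bp, groups[0].end_bp) == (700_000, 720_000)
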