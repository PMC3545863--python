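"""SNP callers: pileup construction, per-line genotyping, the 2-of-3 rule,
the EST caller, and the 50-bp distance filters."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsimark.io_formats import AlignmentRecord, JunctionSet, SequenceRecord
from capsimark.snp_discovery import (
    CandidateSNP,
    ESTColumn,
    GenotypeRow,
    build_pileup,
    call_est_snps,
    call_iga_snps,
    call_line,
    est_columns_from_members,
    filter_est_snps,
    filter_iga_snps,
    genotype_rows,
)


def _aln(read_id, genotype, contig, pos, cigar, seq):
    return AlignmentRecord(read_id, genotype, contig, pos, cigar, seq)


CONTIG = SequenceRecord("c1", "ACGT" * 50)  # 200 nt


class TestBuildPileup:
    def test_single_match_read_covers_its_span(self):
        pile = build_pileup(
            [_aln("r1", "g1", "c1", 1, "85M", "A" * 85)], [CONTIG])
        for pos in (1, 42, 85):
            assert pile.column("c1", pos).counts["g1"] == {"A": 1}
        assert pile.column("c1", 86).counts["g1"] == {}

    def test_genotypes_kept_separate(self):
        pile = build_pileup(
            [_aln("r1", "g1", "c1", 10, "20M", "A" * 20),
             _aln("r2", "g2", "c1", 10, "20M", "C" * 20)], [CONTIG])
        col = pile.column("c1", 15)
        assert col.counts == {"g1": {"A": 1}, "g2": {"C": 1}}

    def test_deletion_consumes_reference_without_counting(self):
        pile = build_pileup(
            [_aln("r1", "g1", "c1", 1, "10M2D10M", "G" * 20)], [CONTIG])
        assert pile.column("c1", 11).counts["g1"] == {}
        assert pile.column("c1", 12).counts["g1"] == {}
        assert pile.column("c1", 13).counts["g1"] == {"G": 1}
        assert pile.column("c1", 22).counts["g1"] == {"G": 1}

    def test_insertion_consumes_read_only(self):
        pile = build_pileup(
            [_aln("r1", "g1", "c1", 1, "5M3I5M", "A" * 5 + "CCC" + "A" * 5)],
            [CONTIG])
        assert pile.column("c1", 6).counts["g1"] == {"A": 1}
        assert pile.column("c1", 10).counts["g1"] == {"A": 1}
        assert pile.column("c1", 11).counts["g1"] == {}

    def test_overrunning_alignment_skipped_and_counted(self):
        pile = build_pileup(
            [_aln("r1", "g1", "c1", 190, "20M", "A" * 20)], [CONTIG])
        assert pile.skipped_overrun == 1
        assert pile.column("c1", 195).counts["g1"] == {}


class TestCallLine:
    @pytest.mark.parametrize("counts,status,base", [
        ({"G": 15}, "hom", "G"),
        ({"G": 9}, "low_depth", "G"),          # one below the 10-read floor
        ({"G": 8, "C": 6}, "het", "G"),        # no base reaches 90 %
        ({"G": 9, "C": 1}, "hom", "G"),        # depth 10, fraction exactly 0.9
        ({"G": 9, "C": 2}, "het", "G"),
        ({"G": 8, "C": 1, "T": 1}, "low_depth", "G"),  # minor too rare for het
        ({}, "low_depth", None),
    ])
    def test_status_rules(self, counts, status, base):
        call = call_line(counts)
        assert (call.status, call.base) == (status, base)

    def test_n_counts_carry_no_information(self):
        assert call_line({"G": 12, "N": 40}).status == "hom"


def _row(g_alleles, pos=500, depth=15, consensus=None):
    calls = {}
    for g, allele in g_alleles.items():
        if allele == "het":
            calls[g] = call_line({"G": depth - depth // 2, "C": depth // 2})
        else:
            calls[g] = call_line({allele: depth})
    consensus = consensus or next(iter(g_alleles.values()))
    return GenotypeRow("c1", pos, consensus, calls)


class TestCallIgaSnps:
    def test_two_vs_one_called(self):
        snps, hets = call_iga_snps(
            [_row({"a": "G", "b": "G", "c": "C"})])
        (s,) = snps
        assert s.alleles == ("G", "C")
        assert s.allele_by_genotype == {"a": "G", "b": "G", "c": "C"}
        assert s.total_depth == 45
        assert hets == []

    def test_unanimous_not_called(self):
        snps, _ = call_iga_snps([_row({"a": "G", "b": "G", "c": "G"})])
        assert snps == []

    def test_het_line_suppresses_call_and_is_tracked(self):
        snps, hets = call_iga_snps(
            [_row({"a": "G", "b": "het", "c": "C"}, pos=77)])
        assert snps == []
        assert hets == [("c1", 77)]

    def test_low_depth_line_suppresses_call(self):
        calls = {"a": call_line({"G": 15}), "b": call_line({"G": 9}),
                 "c": call_line({"C": 15})}
        snps, hets = call_iga_snps([GenotypeRow("c1", 10, "G", calls)])
        assert snps == [] and hets == []

    def test_three_distinct_alleles_not_called(self):
        snps, _ = call_iga_snps([_row({"a": "G", "b": "A", "c": "C"})])
        assert snps == []


class TestFilterIgaSnps:
    def _snp(self, pos, depths=(12, 12, 12)):
        return CandidateSNP("c1", pos, ("G", "C"),
                            {"a": "G", "b": "G", "c": "C"},
                            dict(zip("abc", depths)), sum(depths), "iga")

    def test_near_junction_flagged(self):
        kept, flagged = filter_iga_snps(
            [self._snp(120)], [], JunctionSet({"c1": [150]}))
        assert kept == []
        assert flagged[0].filter_flags == {"near_junction"}

    def test_junction_distance_50_passes(self):
        kept, flagged = filter_iga_snps(
            [self._snp(100)], [], JunctionSet({"c1": [150]}))
        assert flagged == [] and len(kept) == 1

    def test_adjacent_pair_both_flagged(self):
        kept, flagged = filter_iga_snps(
            [self._snp(100), self._snp(149)], [], JunctionSet())
        assert kept == []
        assert all(s.filter_flags == {"adjacent_snp"} for s in flagged)

    def test_snps_50_apart_both_kept(self):
        kept, flagged = filter_iga_snps(
            [self._snp(100), self._snp(150)], [], JunctionSet())
        assert len(kept) == 2 and flagged == []

    def test_adjacent_het_flagged(self):
        kept, flagged = filter_iga_snps(
            [self._snp(500)], [("c1", 530)], JunctionSet())
        assert flagged[0].filter_flags == {"adjacent_het"}

    def test_isolated_snp_kept(self):
        kept, _ = filter_iga_snps(
            [self._snp(500)], [], JunctionSet({"c1": [600]}))
        assert len(kept) == 1

    def test_low_total_depth_flagged(self):
        kept, flagged = filter_iga_snps(
            [self._snp(500, depths=(6, 6, 6))], [], JunctionSet())
        assert flagged[0].filter_flags == {"low_depth_total"}

    def test_per_line_depth_mode(self):
        snp = self._snp(500, depths=(30, 30, 15))
        kept, flagged = filter_iga_snps([snp], [], JunctionSet(),
                                        total_min_depth=20,
                                        depth_mode="per_line")
        assert flagged[0].filter_flags == {"low_depth_total"}


class TestEstCaller:
    def test_columns_from_members_with_gaps(self):
        contig = SequenceRecord("e1", "ACGTACGTAC")
        cols = est_columns_from_members(
            contig, [("ACGT", 1), ("A-GT", 1), ("GTAC", 3)])
        by_pos = {c.pos: c.counts for c in cols}
        assert by_pos[1] == {"A": 2}
        assert by_pos[2] == {"C": 1}  # gap carries no information
        assert by_pos[3] == {"G": 3}

    def test_singleton_contig_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            est_columns_from_members(SequenceRecord("e1", "ACGT"),
                                     [("ACGT", 1)])

    @pytest.mark.parametrize("counts,expected", [
        ({"A": 3, "G": 2}, ("A", "G")),
        ({"A": 5, "G": 1}, None),            # minor allele depth 1 < 2
        ({"A": 2, "C": 8}, ("C", "A")),      # major first
    ])
    def test_min_allele_depth_rule(self, counts, expected):
        snps = call_est_snps([ESTColumn("e1", 7, counts)])
        if expected is None:
            assert snps == []
        else:
            assert snps[0].alleles == expected

    def test_tri_allelic_flagged_with_lexicographic_tie_break(self):
        (s,) = call_est_snps([ESTColumn("e1", 7, {"A": 2, "G": 2, "T": 2})])
        assert s.alleles == ("A", "G")
        assert s.tri_allelic

    def _est(self, pos, depth):
        return CandidateSNP("e1", pos, ("A", "G"), {}, {}, depth, "est")

    def test_near_end_dropped(self):
        kept = filter_est_snps([self._est(40, 10), self._est(460, 10)], 500)
        assert kept == []

    def test_higher_coverage_wins_within_50(self):
        kept = filter_est_snps([self._est(100, 10), self._est(130, 6)], 500)
        assert [s.pos for s in kept] == [100]
        kept = filter_est_snps([self._est(100, 5), self._est(130, 9)], 500)
        assert [s.pos for s in kept] == [130]

    def test_coverage_tie_keeps_leftmost(self):
        kept = filter_est_snps([self._est(100, 8), self._est(130, 8)], 500)
        assert [s.pos for s in kept] == [100]

    def test_reevaluation_against_surviving_snp(self):
        kept = filter_est_snps(
            [self._est(100, 10), self._est(130, 6), self._est(160, 12)], 500)
        assert [s.pos for s in kept] == [100, 160]


class TestRecoveryOnSimulation:
    def test_clean_snps_recovered_exactly(self, called):
        clean = {(v.contig_id, v.pos) for v in called.truth.snps(kinds=("clean",))}
        kept = {(s.contig_id, s.pos) for s in called.kept}
        assert kept == clean

    def test_recovered_alleles_match_planted(self, called):
        planted = {(v.contig_id, v.pos): v.alleles
                   for v in called.truth.snps(kinds=("clean",))}
        for s in called.kept:
            assert s.allele_by_genotype == planted[(s.contig_id, s.pos)]

    def test_violators_carry_their_expected_flag(self, called):
        expected = {"near_junction": "near_junction",
                    "adjacent_pair": "adjacent_snp",
                    "near_het": "adjacent_het"}
        flagged = {(s.contig_id, s.pos): s.filter_flags for s in called.flagged}
        n_checked = 0
        for v in called.truth.snps():
            if v.kind in expected:
                key = (v.contig_id, v.pos)
                assert key in flagged
                assert expected[v.kind] in flagged[key]
                n_checked += 1
        assert n_checked > 0

    def test_het_positions_on_track_not_called(self, called):
        planted_het = {(v.contig_id, v.pos)
                       for v in called.truth.het_positions()}
        assert planted_het <= set(called.het_track)
        called_pos = {(s.contig_id, s.pos) for s in called.candidates}
        assert not (planted_het & called_pos)

    def test_no_kept_pair_within_50bp_and_none_near_junction(self, called):
        by_contig: dict[str, list[int]] = {}
        for s in called.kept:
            by_contig.setdefault(s.contig_id, []).append(s.pos)
        for cid, positions in by_contig.items():
            positions.sort()
            assert all(b - a >= 50 for a, b in zip(positions, positions[1:]))
            for p in positions:
                assert all(abs(p - j) >= 50
                           for j in called.truth.junctions.get(cid))

    def test_candidate_partition_exact(self, called):
        assert len(called.candidates) == len(called.kept) + len(called.flagged)

    def test_raising_min_line_depth_never_adds_snps(self, called):
        base = {(s.contig_id, s.pos) for s in called.candidates}
        rows = genotype_rows(called.pileup, called.truth.contigs,
                             min_line_depth=15)
        higher, _ = call_iga_snps(rows)
        assert {(s.contig_id, s.pos) for s in higher} <= base


@given(st.lists(
    st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 4)),
    min_size=3, max_size=3))
@settings(max_examples=150, deadline=None)
def test_candidate_monotonicity_in_line_depth(line_counts):
    """Any position called a SNP at a stricter depth floor is also called at
    the looser floor."""
    def rows(min_depth):
        calls = {f"g{i}": call_line({"G": a, "C": b, "T": c},
                                    min_line_depth=min_depth)
                 for i, (a, b, c) in enumerate(line_counts)}
        return [GenotypeRow("c1", 100, "G", calls)]

    strict, _ = call_iga_snps(rows(14))
    loose, _ = call_iga_snps(rows(10))
    assert {(s.pos, s.alleles) for s in strict} <= {(s.pos, s.alleles)
                                                   for s in loose}
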