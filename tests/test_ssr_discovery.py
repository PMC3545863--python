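"""SSR scanner vs a brute-force oracle, compound merging, canonical motif
classes, cross-assembly matching and Primer3 task round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capsimark as cm
from capsimark.io_formats import SequenceRecord
from capsimark.ssr_discovery import (
    DEFAULT_MAX_SPACER,
    SSRRecord,
    canonical_motif,
    find_perfect_ssrs,
    make_primer3_input,
    match_ssrs_across_assemblies,
    merge_compound,
    parse_primer3_output,
    ssr_frame,
)
from capsimark.synthetic_data import DEFAULT_SSR_THRESHOLDS, revcomp

from oracles import brute_ssrs


def _tuples(records):
    return {(r.start, r.unit_size, r.repeat_count) for r in records}


class TestScanner:
    def test_dinucleotide_threshold_exactly_met(self):
        (r,) = find_perfect_ssrs("ACACACACACAC")
        assert (r.motif, r.repeat_count, r.start, r.end) == ("AC", 6, 1, 12)

    def test_below_threshold_not_reported(self):
        assert find_perfect_ssrs("ACACACACAC") == []

    def test_leftmost_maximal_frame(self):
        # the maximal tandem starts one base left of the AAG frame
        (r,) = find_perfect_ssrs("GGAAGAAGAAGAAGAAGCC")
        assert (r.start, r.motif, r.repeat_count) == (2, "GAA", 5)

    def test_reducible_motif_reported_at_smallest_unit(self):
        records = find_perfect_ssrs("ATATATATATAT")
        assert [(r.motif, r.repeat_count) for r in records] == [("AT", 6)]

    def test_n_breaks_runs(self):
        assert find_perfect_ssrs("ACACACACACNACACACACAC") == []
        seq = "ACACACACACACNACACACACACAC"
        assert _tuples(find_perfect_ssrs(seq)) == {(1, 2, 6), (14, 2, 6)}

    def test_embedded_in_random_context(self):
        rng = np.random.default_rng(0)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        seq = flank + "AAG" * 7 + flank[::-1]
        found = find_perfect_ssrs(seq)
        assert any(r.motif in ("AAG", "AGA", "GAA") and r.repeat_count >= 7
                   for r in found)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            seq = "".join("ACGTN"[i] for i in
                          rng.choice(5, size=1500, p=[.24, .24, .24, .24, .04]))
            # salt with a few planted repeats so non-trivial cases occur
            for _ in range(3):
                u = int(rng.integers(2, 7))
                motif = "".join("ACGT"[i] for i in rng.integers(0, 4, u))
                pos = int(rng.integers(0, len(seq) - 40))
                rep = int(rng.integers(4, 8))
                seq = seq[:pos] + motif * rep + seq[pos + u * rep:]
            assert _tuples(find_perfect_ssrs(seq)) \
                == brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)

    def test_planted_ssrs_recovered_exactly(self, truth):
        assert truth.ssrs  # fixture seed guarantees planted SSRs
        for contig in truth.contigs:
            found = find_perfect_ssrs(contig.sequence, contig_id=contig.id)
            got = {(r.contig_id, r.start, r.motif, r.repeat_count)
                   for r in found}
            for s in truth.ssrs:
                if s.contig_id == contig.id:
                    assert (s.contig_id, s.start, s.motif, s.count) in got


class TestCompoundMerging:
    def _ssr(self, start, motif, count):
        u = len(motif)
        return SSRRecord("c1", start, start + u * count - 1, motif, count)

    def test_short_gap_merges(self):
        seq = "AC" * 6 + "TT" + "AG" * 6
        perfect, compounds = merge_compound(
            [self._ssr(1, "AC", 6), self._ssr(15, "AG", 6)], seq=seq)
        assert perfect == []
        (c,) = compounds
        assert c.formatted() == "(AC)6tt(AG)6"
        assert (c.start, c.end) == (1, 26)

    def test_gap_101_stays_perfect(self):
        perfect, compounds = merge_compound(
            [self._ssr(1, "AC", 6), self._ssr(114, "AG", 6)],
            max_spacer=DEFAULT_MAX_SPACER)
        assert len(perfect) == 2 and compounds == []

    def test_gap_100_merges(self):
        perfect, compounds = merge_compound(
            [self._ssr(1, "AC", 6), self._ssr(113, "AG", 6)])
        assert perfect == [] and len(compounds) == 1

    def test_three_members_chain(self):
        perfect, compounds = merge_compound(
            [self._ssr(1, "AC", 6), self._ssr(23, "AG", 6),
             self._ssr(45, "AAT", 5)])
        (c,) = compounds
        assert len(c.members) == 3 and perfect == []

    def test_every_input_in_exactly_one_output(self):
        ssrs = [self._ssr(1, "AC", 6), self._ssr(200, "AG", 6),
                self._ssr(220, "AT", 6), self._ssr(500, "AAC", 5)]
        perfect, compounds = merge_compound(ssrs)
        n_out = len(perfect) + sum(len(c.members) for c in compounds)
        assert n_out == len(ssrs)


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("CT", "AG/CT"),
        ("AG", "AG/CT"),
        ("GTT", "AAC/GTT"),
        ("TA", "AT/TA"),
        ("AT", "AT/TA"),
        ("AC", "AC/GT"),
    ])
    def test_field_convention_labels(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ANG")

    @given(st.text(alphabet="ACGT", min_size=2, max_size=6),
           st.integers(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_rotation_and_revcomp(self, motif, shift):
        rotated = motif[shift % len(motif):] + motif[:shift % len(motif)]
        cls = canonical_motif(motif)
        assert canonical_motif(rotated) == cls
        assert canonical_motif(revcomp(motif)) == cls
        rep = cls.split("/")[0]
        assert canonical_motif(rep) == cls  # idempotent on the representative


class TestCrossAssemblyMatch:
    def _assembly(self, seed):
        rng = np.random.default_rng(seed)
        contigs = {}
        ssrs = []
        for i in range(4):
            flank = "".join("ACGT"[j] for j in rng.integers(0, 4, 150))
            flank2 = "".join("ACGT"[j] for j in rng.integers(0, 4, 150))
            seq = flank + "AG" * 7 + flank2
            cid = f"s{seed}_{i}"
            contigs[cid] = seq
            ssrs.append(SSRRecord(cid, 151, 164, "AG", 7))
        return contigs, ssrs

    def test_identical_contigs_all_matched(self):
        contigs, ssrs = self._assembly(1)
        pairs = match_ssrs_across_assemblies(ssrs, contigs, ssrs, contigs)
        assert len(pairs) == len(ssrs)
        assert all(a.contig_id == b.contig_id for a, b, _ in pairs)

    def test_same_motif_different_context_not_matched(self):
        contigs_a, ssrs_a = self._assembly(1)
        contigs_b, ssrs_b = self._assembly(2)
        assert match_ssrs_across_assemblies(
            ssrs_a, contigs_a, ssrs_b, contigs_b) == []

    def test_different_repeat_count_not_matched(self):
        contigs, ssrs = self._assembly(1)
        contigs_b = {cid: seq.replace("AG" * 7, "AG" * 8)
                     for cid, seq in contigs.items()}
        ssrs_b = [SSRRecord(r.contig_id, 151, 166, "AG", 8) for r in ssrs]
        assert match_ssrs_across_assemblies(
            ssrs, contigs, ssrs_b, contigs_b) == []


class TestPrimerTasks:
    def test_target_span_and_policy(self):
        contig = SequenceRecord("c1", "T" * 119 + "AC" * 6 + "G" * 150)
        rec = SSRRecord("c1", 120, 131, "AC", 6)
        task = make_primer3_input(rec, contig)
        text = task.to_boulder()
        assert "SEQUENCE_TARGET=120,12" in text
        assert "PRIMER_PRODUCT_SIZE_RANGE=100-300" in text
        assert "PRIMER_OPT_TM=60" in text
        assert "PRIMER_OPT_SIZE=20" in text
        assert not task.edge_warning

    def test_ssr_flush_to_contig_start_warned(self):
        contig = SequenceRecord("c1", "AC" * 6 + "G" * 100)
        task = make_primer3_input(SSRRecord("c1", 1, 12, "AC", 6), contig)
        assert task.edge_warning

    def test_parse_output_round_trip(self):
        text = (
            "SEQUENCE_ID=c1_120\n"
            "PRIMER_LEFT_0_SEQUENCE=ACGTACGTACGTACGTACGT\n"
            "PRIMER_RIGHT_0_SEQUENCE=TGCATGCATGCATGCATGCA\n"
            "PRIMER_LEFT_0_TM=59.8\n"
            "PRIMER_RIGHT_0_TM=60.2\n"
            "PRIMER_PAIR_0_PRODUCT_SIZE=180\n"
            "=\n")
        parsed = parse_primer3_output(text)
        (pair,) = parsed["c1_120"]
        assert pair["left"].startswith("ACGT")
        assert pair["product_size"] == 180
        assert pair["right_tm"] == 60.2


def test_ssr_frame_misa_layout():
    recs = [SSRRecord("c1", 10, 21, "AC", 6)]
    df = ssr_frame(recs)
    assert list(df.columns) == ["ID", "SSR nr.", "SSR type", "SSR", "size",
                                "start", "end", "canonical_class"]
    assert df.iloc[0]["SSR"] == "(AC)6"
    assert df.iloc[0]["canonical_class"] == "AC/GT"
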