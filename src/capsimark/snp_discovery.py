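"""SNP callers for the two assembly types, plus the distance filters.

Two callers are implemented:

* the **three-genotype pileup caller** ("iga" source): reads from each
  homozygous line are piled up on the consensus contigs; per line a position
  is genotyped homozygous, heterozygous or low-depth, and a putative SNP is
  called where two lines share a homozygous allele and the third line is
  homozygous for a different allele (the 2-of-3 rule). Positions with any
  heterozygous line call are kept on a separate track and poison nearby
  SNPs through the adjacency filter.

* the **EST alignment caller** ("est" source): member sequences of a
  multi-EST contig are piled up on the contig consensus; a position is a
  putative SNP when at least two distinct bases each reach the minimum
  allele depth (default 2). Singleton contigs cannot be examined.

Distance filters follow a 50-bp exclusion radius: a kept SNP must lie at
least 50 bp from every exon-exon junction, every other candidate SNP and
every heterozygous position ("at least 50 bp" is read as >= 50: a distance
of 49 fails, 50 passes); plus a total-depth floor for the pileup caller and
a contig-end / higher-coverage-wins rule for the EST caller.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, JunctionSet, SequenceRecord, parse_cigar

#: base codes used by the pileup arrays; row 4 tallies N (no-information).
_BASE_ORDER = "ACGT"
_CODE: np.ndarray = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASE_ORDER):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

DEFAULT_MIN_LINE_DEPTH = 10
DEFAULT_HOM_FRACTION = 0.9
DEFAULT_HET_MIN_COUNT = 2
DEFAULT_WINDOW = 50
DEFAULT_TOTAL_MIN_DEPTH = 20
DEFAULT_EST_MIN_ALLELE_DEPTH = 2


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupColumn:
    """Per-position, per-genotype base counts (1-based position)."""

    contig_id: str
    pos: int
    counts: dict[str, dict[str, int]]

    def genotype_counts(self, genotype: str) -> dict[str, int]:
        return self.counts.get(genotype, {})


class Pileup:
    """Per-contig, per-genotype base-count matrices built from alignments.

    Internally a (5, L) int32 array per (contig, genotype): rows A, C, G, T
    and N; deletions consume reference without contributing a base count.
    """

    def __init__(self, contig_lengths: Mapping[str, int], genotypes: Sequence[str]):
        self.contig_lengths = dict(contig_lengths)
        self.genotypes = list(genotypes)
        self._mat: dict[str, dict[str, np.ndarray]] = {
            c: {g: np.zeros((5, L), dtype=np.int32) for g in self.genotypes}
            for c, L in self.contig_lengths.items()
        }
        self.skipped_overrun = 0

    def matrix(self, contig_id: str, genotype: str) -> np.ndarray:
        return self._mat[contig_id][genotype]

    def column(self, contig_id: str, pos: int) -> PileupColumn:
        """Counts at a 1-based position."""
        counts = {}
        for g in self.genotypes:
            col = self._mat[contig_id][g][:, pos - 1]
            counts[g] = {b: int(col[i]) for i, b in enumerate(_BASE_ORDER) if col[i]}
        return PileupColumn(contig_id, pos, counts)

    def iter_columns(self, contig_id: str, covered_only: bool = True,
                     ) -> Iterator[PileupColumn]:
        L = self.contig_lengths[contig_id]
        depth = np.zeros(L, dtype=np.int64)
        for g in self.genotypes:
            depth += self._mat[contig_id][g][:4].sum(axis=0)
        positions = np.flatnonzero(depth) + 1 if covered_only else range(1, L + 1)
        for pos in positions:
            yield self.column(contig_id, int(pos))


def build_pileup(
    alignments: Iterable[AlignmentRecord],
    contigs: Sequence[SequenceRecord] | Mapping[str, int],
    genotypes: Sequence[str] | None = None,
) -> Pileup:
    """Accumulate cigar-aware base counts from an alignment stream.

    M consumes read and reference, I consumes read only, D consumes
    reference only (no base counted), S is ignored read-side padding.
    Alignments overrunning the contig end are skipped and counted.
    """
    if isinstance(contigs, Mapping):
        lengths = dict(contigs)
    else:
        lengths = {c.id: len(c) for c in contigs}
    alignments = list(alignments)
    if genotypes is None:
        seen = []
        for a in alignments:
            if a.genotype_tag not in seen:
                seen.append(a.genotype_tag)
        genotypes = seen
    pile = Pileup(lengths, genotypes)

    # batch (code,row) index pairs per contig+genotype, one add.at per batch
    batches: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = defaultdict(list)
    for a in alignments:
        L = lengths.get(a.contig_id)
        if L is None or a.pos - 1 + a.reference_span() > L:
            pile.skipped_overrun += 1
            continue
        codes = _CODE[np.frombuffer(a.sequence.encode(), dtype=np.uint8)]
        ref = a.pos - 1
        rd = 0
        for n, op in parse_cigar(a.cigar):
            if op == "M":
                batches[(a.contig_id, a.genotype_tag)].append(
                    (codes[rd:rd + n], np.arange(ref, ref + n)))
                ref += n
                rd += n
            elif op == "I" or op == "S":
                rd += n
            elif op == "D":
                ref += n
    for (cid, g), parts in batches.items():
        rows = np.concatenate([p[0] for p in parts])
        cols = np.concatenate([p[1] for p in parts])
        np.add.at(pile.matrix(cid, g), (rows, cols), 1)
    return pile


# ---------------------------------------------------------------------------
# per-line genotype calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineCall:
    """Genotype call of one line at one position."""

    status: str  # "hom" | "het" | "low_depth"
    base: str | None  # homozygous allele, or major base for het
    second: str | None  # minor base for het calls
    depth: int
    major_fraction: float

    @property
    def is_hom(self) -> bool:
        return self.status == "hom"

    @property
    def is_het(self) -> bool:
        return self.status == "het"


def call_line(
    counts: Mapping[str, int],
    min_line_depth: int = DEFAULT_MIN_LINE_DEPTH,
    hom_fraction: float = DEFAULT_HOM_FRACTION,
    het_min_count: int = DEFAULT_HET_MIN_COUNT,
) -> LineCall:
    """Genotype one line from its ACGT base counts.

    hom(b): depth >= min_line_depth and count(b)/depth >= hom_fraction.
    het: depth >= min_line_depth, no base reaches hom_fraction, and the
    second-most-frequent base has count >= het_min_count.
    low_depth otherwise. N counts carry no information and are ignored.
    """
    acgt = [(counts.get(b, 0), b) for b in _BASE_ORDER]
    depth = sum(c for c, _ in acgt)
    if depth == 0:
        return LineCall("low_depth", None, None, 0, 0.0)
    # sort by count desc, base asc (lexicographic tie-break)
    ordered = sorted(acgt, key=lambda t: (-t[0], t[1]))
    (c1, b1), (c2, b2) = ordered[0], ordered[1]
    frac = c1 / depth
    if depth < min_line_depth:
        return LineCall("low_depth", b1, None, depth, frac)
    if frac >= hom_fraction:
        return LineCall("hom", b1, None, depth, frac)
    if c2 >= het_min_count:
        return LineCall("het", b1, b2, depth, frac)
    return LineCall("low_depth", b1, None, depth, frac)


@dataclass(frozen=True)
class GenotypeRow:
    """Per-position alignment of the consensus base with all line calls."""

    contig_id: str
    pos: int
    consensus: str
    calls: dict[str, LineCall]


def genotype_rows(
    pileup: Pileup,
    contigs: Sequence[SequenceRecord],
    min_line_depth: int = DEFAULT_MIN_LINE_DEPTH,
    hom_fraction: float = DEFAULT_HOM_FRACTION,
    het_min_count: int = DEFAULT_HET_MIN_COUNT,
    include_all: bool = False,
) -> Iterator[GenotypeRow]:
    """Generate genotype-table rows from a pileup.

    By default only *informative* positions are yielded: those where some
    line call is heterozygous, or where every line is called and the
    homozygous alleles are not unanimous consensus matches. ``include_all``
    yields every covered position (slow; for inspection).
    """
    seqs = {c.id: c.sequence for c in contigs}
    for cid, L in pileup.contig_lengths.items():
        if cid not in seqs:
            continue
        mats = [pileup.matrix(cid, g)[:4].astype(np.int64) for g in pileup.genotypes]
        depths = [m.sum(axis=0) for m in mats]
        majors = [m.argmax(axis=0) for m in mats]
        maxc = [m.max(axis=0) for m in mats]
        sorted_desc = [np.sort(m, axis=0)[::-1] for m in mats]
        seconds = [s[1] for s in sorted_desc]

        # fraction arithmetic kept identical to call_line (mc/d vs threshold)
        fracs = [np.divide(mc, d, out=np.zeros(len(d)), where=d > 0)
                 for d, mc in zip(depths, maxc)]
        hom = [(d >= min_line_depth) & (fr >= hom_fraction) & (d > 0)
               for d, fr in zip(depths, fracs)]
        het = [(d >= min_line_depth) & (fr < hom_fraction)
               & (sc >= het_min_count)
               for d, fr, sc in zip(depths, fracs, seconds)]

        any_het = np.logical_or.reduce(het)
        all_hom = np.logical_and.reduce(hom)
        major_arr = np.stack(majors)
        disagree = (major_arr != major_arr[0]).any(axis=0)
        consensus_codes = _CODE[np.frombuffer(seqs[cid].encode(), dtype=np.uint8)]
        off_consensus = (major_arr != consensus_codes[None, :]).any(axis=0)

        if include_all:
            interesting = np.flatnonzero(np.stack(depths).sum(axis=0) > 0)
        else:
            interesting = np.flatnonzero(
                any_het | (all_hom & (disagree | off_consensus)))
        for i in interesting:
            pos = int(i) + 1
            calls = {}
            for g in pileup.genotypes:
                col = pileup.matrix(cid, g)[:, i]
                counts = {b: int(col[j]) for j, b in enumerate(_BASE_ORDER)}
                calls[g] = call_line(counts, min_line_depth, hom_fraction,
                                     het_min_count)
            yield GenotypeRow(cid, pos, seqs[cid][i], calls)


# ---------------------------------------------------------------------------
# candidate SNPs
# ---------------------------------------------------------------------------

@dataclass
class CandidateSNP:
    """A putative biallelic SNP with per-genotype alleles and filter flags."""

    contig_id: str
    pos: int
    alleles: tuple[str, str]  # (majority/REF, minority/ALT)
    allele_by_genotype: dict[str, str]
    depth_by_genotype: dict[str, int]
    total_depth: int
    source: str  # "est" | "iga"
    filter_flags: set[str] = field(default_factory=set)
    tri_allelic: bool = False

    def ref_alt(self) -> tuple[str, str]:
        return self.alleles


def call_iga_snps(
    rows: Iterable[GenotypeRow],
) -> tuple[list[CandidateSNP], list[tuple[str, int]]]:
    """Apply the 2-of-3 homozygote rule to a genotype-table row stream.

    Returns the candidate SNPs plus the heterozygous-position track (any
    row with at least one het line call) consumed by the adjacency filter.
    A SNP requires every line homozygous at adequate depth, exactly two
    distinct alleles, with two lines sharing one allele and the third line
    carrying the other.
    """
    snps: list[CandidateSNP] = []
    het_positions: list[tuple[str, int]] = []
    for row in rows:
        calls = row.calls
        if any(c.is_het for c in calls.values()):
            het_positions.append((row.contig_id, row.pos))
            continue
        if not all(c.is_hom for c in calls.values()):
            continue
        alleles = {g: c.base for g, c in calls.items()}
        distinct = sorted(set(alleles.values()))
        if len(distinct) != 2:
            continue
        n_by_allele = {a: sum(1 for v in alleles.values() if v == a)
                       for a in distinct}
        # two lines share one allele, the third differs
        if sorted(n_by_allele.values()) != [1, len(calls) - 1]:
            continue
        major = max(distinct, key=lambda a: n_by_allele[a])
        minor = min(distinct, key=lambda a: n_by_allele[a])
        depths = {g: c.depth for g, c in calls.items()}
        snps.append(CandidateSNP(
            contig_id=row.contig_id, pos=row.pos,
            alleles=(major, minor),
            allele_by_genotype=alleles,
            depth_by_genotype=depths,
            total_depth=sum(depths.values()),
            source="iga"))
    return snps, het_positions


def filter_iga_snps(
    snps: Sequence[CandidateSNP],
    het_positions: Iterable[tuple[str, int]],
    junctions: JunctionSet,
    window: int = DEFAULT_WINDOW,
    total_min_depth: int = DEFAULT_TOTAL_MIN_DEPTH,
    depth_mode: str = "summed",
) -> tuple[list[CandidateSNP], list[CandidateSNP]]:
    """Distance + depth filtering of pileup-called SNPs.

    A SNP is kept iff its distance to every junction coordinate, every other
    candidate SNP and every heterozygous position is >= ``window``, and its
    read depth passes the floor (``depth_mode='summed'``: total across lines
    >= total_min_depth; ``'per_line'``: every line >= total_min_depth).
    Rejected SNPs carry the specific flag(s); returns (kept, flagged).
    """
    if depth_mode not in ("summed", "per_line"):
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    het_by_contig: dict[str, list[int]] = defaultdict(list)
    for cid, pos in het_positions:
        het_by_contig[cid].append(pos)
    snp_by_contig: dict[str, list[CandidateSNP]] = defaultdict(list)
    for s in snps:
        snp_by_contig[s.contig_id].append(s)

    kept: list[CandidateSNP] = []
    flagged: list[CandidateSNP] = []
    for cid, group in snp_by_contig.items():
        jx = junctions.get(cid)
        hets = sorted(het_by_contig.get(cid, []))
        positions = sorted(s.pos for s in group)
        for s in sorted(group, key=lambda x: x.pos):
            if any(abs(s.pos - j) < window for j in jx):
                s.filter_flags.add("near_junction")
            if any(abs(s.pos - p) < window for p in positions if p != s.pos):
                s.filter_flags.add("adjacent_snp")
            if any(abs(s.pos - h) < window for h in hets):
                s.filter_flags.add("adjacent_het")
            if depth_mode == "summed":
                if s.total_depth < total_min_depth:
                    s.filter_flags.add("low_depth_total")
            else:
                if min(s.depth_by_genotype.values(), default=0) < total_min_depth:
                    s.filter_flags.add("low_depth_total")
            (flagged if s.filter_flags else kept).append(s)
    kept.sort(key=lambda s: (s.contig_id, s.pos))
    flagged.sort(key=lambda s: (s.contig_id, s.pos))
    return kept, flagged


# ---------------------------------------------------------------------------
# EST-alignment caller
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ESTColumn:
    """Base counts across the aligned member ESTs of one contig position."""

    contig_id: str
    pos: int
    counts: dict[str, int]


def est_columns_from_members(
    contig: SequenceRecord,
    members: Sequence[tuple[str, int]],
) -> list[ESTColumn]:
    """Pile up ungapped member sequences on their consensus contig.

    ``members`` are (sequence, 1-based start on contig) pairs; gap characters
    ('-') and N contribute no information. Contigs assembled from fewer than
    two members cannot be examined for SNPs and raise ValueError.
    """
    if len(members) < 2:
        raise ValueError(
            f"contig {contig.id!r}: singleton contigs cannot be examined")
    L = len(contig)
    counts = np.zeros((5, L), dtype=np.int32)
    for seq, start in members:
        seq = seq.upper()
        if start < 1 or start - 1 + len(seq) > L:
            raise ValueError(
                f"member alignment overruns contig {contig.id!r}")
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        np.add.at(counts, (codes, np.arange(start - 1, start - 1 + len(seq))), 1)
    out = []
    for i in np.flatnonzero(counts[:4].sum(axis=0)):
        col = counts[:4, i]
        out.append(ESTColumn(contig.id, int(i) + 1,
                             {b: int(col[j]) for j, b in enumerate(_BASE_ORDER)
                              if col[j]}))
    return out


def call_est_snps(
    columns: Iterable[ESTColumn],
    min_allele_depth: int = DEFAULT_EST_MIN_ALLELE_DEPTH,
) -> list[CandidateSNP]:
    """Emit a SNP where >= 2 distinct bases each reach min_allele_depth.

    The two highest-count alleles are reported (count ties broken
    lexicographically); columns where a third base also qualifies are
    emitted with ``tri_allelic=True`` so downstream steps can exclude them.
    """
    out: list[CandidateSNP] = []
    for col in columns:
        qualifying = sorted(
            ((c, b) for b, c in col.counts.items()
             if b in _BASE_ORDER and c >= min_allele_depth),
            key=lambda t: (-t[0], t[1]))
        if len(qualifying) < 2:
            continue
        (c1, b1), (c2, b2) = qualifying[0], qualifying[1]
        total = sum(c for b, c in col.counts.items() if b in _BASE_ORDER)
        out.append(CandidateSNP(
            contig_id=col.contig_id, pos=col.pos,
            alleles=(b1, b2), allele_by_genotype={},
            depth_by_genotype={}, total_depth=total,
            source="est", tri_allelic=len(qualifying) > 2))
    return out


def filter_est_snps(
    snps: Sequence[CandidateSNP],
    contig_len: int,
    end_window: int = DEFAULT_WINDOW,
    adjacency_window: int = DEFAULT_WINDOW,
) -> list[CandidateSNP]:
    """Contig-end and adjacency filtering of EST-called SNPs on one contig.

    Positions within the first or last ``end_window`` bases are dropped
    (flagged near_end). The survivors are scanned left to right: whenever a
    SNP lies closer than ``adjacency_window`` to the current survivor, only
    the one with higher total coverage is kept (tie -> leftmost), and later
    SNPs are re-evaluated against the kept survivor.
    """
    inside = []
    for s in sorted(snps, key=lambda x: x.pos):
        if s.pos <= end_window or s.pos > contig_len - end_window:
            s.filter_flags.add("near_end")
            continue
        inside.append(s)
    kept: list[CandidateSNP] = []
    for s in inside:
        if kept and s.pos - kept[-1].pos < adjacency_window:
            if s.total_depth > kept[-1].total_depth:
                kept[-1].filter_flags.add("adjacent_snp")
                kept[-1] = s
            else:
                s.filter_flags.add("adjacent_snp")
        else:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# convenience table
# ---------------------------------------------------------------------------

def snp_frame(snps: Sequence[CandidateSNP]) -> pd.DataFrame:
    """Tabulate candidate SNPs (contig, pos, alleles, depths, flags)."""
    rows = []
    for s in snps:
        row = {"contig": s.contig_id, "pos": s.pos, "ref": s.alleles[0],
               "alt": s.alleles[1], "total_depth": s.total_depth,
               "source": s.source,
               "flags": ";".join(sorted(s.filter_flags)) or "PASS"}
        for g, a in s.allele_by_genotype.items():
            row[f"allele_{g}"] = a
        for g, d in s.depth_by_genotype.items():
            row[f"depth_{g}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
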