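"""Readers and writers for the standard formats the marker pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython's SeqIO, SAM parsing to
pysam; this module adds the validation the downstream callers rely on
(uppercase ACGTN alphabet, Phred+33 qualities, a restricted CIGAR alphabet)
and the small tab-separated side formats (junction tables, truth tables,
marker tables).

Coordinate convention: in-memory positions are 0-based half-open wherever a
span is involved; every serialized coordinate (VCF, TSV tables) is 1-based
inclusive, matching the conventions of those formats.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("capsimark")

VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations the pipeline understands. Spliced (N) alignments are
#: rejected: reads are mapped against transcript contigs, never genomic DNA.
SUPPORTED_CIGAR_OPS = frozenset("MIDS")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A contig/unigene: id token, free-text description, ACGTN sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a whitespace-free token: {self.id!r}")
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred scores (the unit of trimming)."""

    id: str
    sequence: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 93):
            raise FormatError(f"read {self.id!r}: Phred scores outside 0-93")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped-or-simple-gapped placement of a read on a contig.

    ``pos`` is the 1-based leftmost mapped reference position. Only the CIGAR
    ops M, I, D and S are allowed; the read-consuming ops (M, I, S) must sum
    to the read length.
    """

    read_id: str
    genotype_tag: str
    contig_id: str
    pos: int
    cigar: str
    sequence: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"alignment {self.read_id!r}: pos must be >= 1")
        consumed = 0
        for length, op in parse_cigar(self.cigar):
            if op in "MIS":
                consumed += length
        if consumed != len(self.sequence):
            raise FormatError(
                f"alignment {self.read_id!r}: cigar {self.cigar} consumes "
                f"{consumed} read bases but sequence has {len(self.sequence)}"
            )

    def reference_span(self) -> int:
        """Number of reference bases covered (M and D ops)."""
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MD")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string, restricted to the M/I/D/S subset."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR string: {cigar!r}")
    out = []
    for n, op in ops:
        if op not in SUPPORTED_CIGAR_OPS:
            raise FormatError(
                f"CIGAR op {op!r} in {cigar!r} is unsupported; spliced/clipped "
                "alignments other than M/I/D/S are not meaningful against "
                "transcript contigs"
            )
        out.append((int(n), op))
    return out


class JunctionSet:
    """Exon-exon junction coordinates per contig.

    A junction coordinate is the 1-based position of the last base of the
    upstream exon on the transcript contig. Coordinates are kept strictly
    increasing per contig.
    """

    def __init__(self, junctions: Mapping[str, Iterable[int]] | None = None):
        self._by_contig: dict[str, list[int]] = {}
        if junctions:
            for contig, coords in junctions.items():
                for c in coords:
                    self.add(contig, c)

    def add(self, contig_id: str, coord: int) -> None:
        if coord < 1:
            raise FormatError(f"junction coordinate must be >= 1, got {coord}")
        lst = self._by_contig.setdefault(contig_id, [])
        if lst and coord <= lst[-1]:
            import bisect
            i = bisect.bisect_left(lst, coord)
            if i < len(lst) and lst[i] == coord:
                return
            lst.insert(i, coord)
        else:
            lst.append(coord)

    def get(self, contig_id: str) -> list[int]:
        return self._by_contig.get(contig_id, [])

    def contigs(self) -> list[str]:
        return sorted(self._by_contig)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_contig.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, JunctionSet) and self._by_contig == other._by_contig

    def validate_against(self, contig_lengths: Mapping[str, int]) -> None:
        """Check every coordinate lies in [1, contig length - 1]."""
        for contig, coords in self._by_contig.items():
            if contig not in contig_lengths:
                raise FormatError(f"junctions reference unknown contig {contig!r}")
            if coords and coords[-1] > contig_lengths[contig] - 1:
                raise FormatError(
                    f"junction {coords[-1]} beyond end of contig {contig!r} "
                    f"(length {contig_lengths[contig]})"
                )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

class AlphabetCounter:
    """Tallies non-ACGTN characters mapped to N on read."""

    def __init__(self) -> None:
        self.n_mapped = 0

    def clean(self, seq: str) -> str:
        seq = seq.upper()
        cleaned, n = _NON_ACGTN.subn("N", seq)
        if n:
            self.n_mapped += n
        return cleaned


def read_fasta(path: str | Path, counter: AlphabetCounter | None = None) -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from a FASTA file, in file order.

    Lowercase is lifted to uppercase; IUPAC ambiguity codes other than N are
    mapped to N and counted (the callers treat non-ACGT as no-information).
    An empty sequence body is a format error.
    """
    counter = counter or AlphabetCounter()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: FASTA must start with '>'")
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        seq = counter.clean(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {i} ({rec.id!r}): empty sequence body")
        yield SequenceRecord(id=rec.id, sequence=seq, description=rec.description)
    if counter.n_mapped:
        logger.warning("%s: %d non-ACGTN characters mapped to N", path, counter.n_mapped)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else rec.description if rec.description.startswith(rec.id) \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Stream QualityReads from a 4-line FASTQ file (Phred+33 only)."""
    counter = AlphabetCounter()
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            yield QualityRead(id=rec.id, sequence=counter.clean(str(rec.seq)), quals=quals)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class SamReadStats:
    """Per-file tally of records skipped while reading SAM."""

    mapped: int = 0
    unmapped: int = 0
    secondary: int = 0
    overrun: int = 0


def read_sam(
    path: str | Path,
    line_tag_rule: Callable[[pysam.AlignedSegment], str] | Mapping[str, str] | str,
    stats: SamReadStats | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM file.

    ``line_tag_rule`` assigns each record to a genotype line: either a fixed
    tag (str), a mapping from read-group id (RG tag) to tag, or a callable on
    the pysam record. Unmapped and secondary/supplementary records are
    skipped and counted. CIGAR ops outside M/I/D/S raise FormatError.
    """
    stats = stats if stats is not None else SamReadStats()
    if isinstance(line_tag_rule, str):
        tag_of = lambda rec: line_tag_rule  # noqa: E731
    elif isinstance(line_tag_rule, Mapping):
        mapping = dict(line_tag_rule)
        tag_of = lambda rec: mapping[rec.get_tag("RG")]  # noqa: E731
    else:
        tag_of = line_tag_rule

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.secondary += 1
                continue
            yield AlignmentRecord(
                read_id=rec.query_name,
                genotype_tag=tag_of(rec),
                contig_id=rec.reference_name,
                pos=rec.reference_start + 1,
                cigar=rec.cigarstring,
                sequence=rec.query_sequence.upper(),
            )
            stats.mapped += 1
    if stats.unmapped or stats.secondary:
        logger.info(
            "%s: skipped %d unmapped, %d secondary records",
            path, stats.unmapped, stats.secondary,
        )


def write_sam(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write alignments as SAM text with a minimal header (RG = genotype)."""
    alignments = list(alignments)
    groups = sorted({a.genotype_tag for a in alignments})
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig in sorted(contig_lengths):
            fh.write(f"@SQ\tSN:{contig}\tLN:{contig_lengths[contig]}\n")
        for g in groups:
            fh.write(f"@RG\tID:{g}\tSM:{g}\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t0\t{a.contig_id}\t{a.pos}\t60\t{a.cigar}\t*\t0\t0\t"
                f"{a.sequence}\t*\tRG:Z:{a.genotype_tag}\n"
            )


# ---------------------------------------------------------------------------
# junction and truth tables
# ---------------------------------------------------------------------------

def read_junction_tsv(path: str | Path) -> JunctionSet:
    """Read a 2-column TSV (contig_id, 1-based junction coordinate)."""
    js = JunctionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            try:
                js.add(parts[0], int(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return js


def write_junction_tsv(junctions: JunctionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig in junctions.contigs():
            for coord in junctions.get(contig):
                fh.write(f"{contig}\t{coord}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_snp_vcf(
    snps: Iterable["CandidateSNP"],  # noqa: F821 - see snp_discovery
    contigs: Mapping[str, int],
    path: str | Path,
    emit_all: bool = False,
) -> None:
    """Write candidate SNPs as VCF 4.2 text.

    REF is the majority-genotype allele, ALT the minority allele; per-genotype
    calls and depths go in the sample columns. SNPs carrying filter flags are
    written only in ``emit_all`` mode, with the failing rule names in FILTER.
    """
    snps = list(snps)
    genotypes: list[str] = []
    for s in snps:
        for g in s.allele_by_genotype:
            if g not in genotypes:
                genotypes.append(g)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=capsimark\n")
        for contig in sorted(contigs):
            fh.write(f"##contig=<ID={contig},length={contigs[contig]}>\n")
        for flag in ("near_end", "near_junction", "adjacent_snp", "adjacent_het",
                     "low_depth_total"):
            fh.write(f'##FILTER=<ID={flag},Description="failed {flag} rule">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT"] + genotypes
        fh.write("\t".join(cols) + "\n")
        for s in snps:
            if s.filter_flags and not emit_all:
                continue
            if s.pos < 1 or s.pos > contigs.get(s.contig_id, 0):
                raise FormatError(
                    f"SNP at {s.contig_id}:{s.pos} outside contig bounds"
                )
            ref, alt = s.ref_alt()
            filt = ";".join(sorted(s.filter_flags)) if s.filter_flags else "PASS"
            samples = []
            for g in genotypes:
                allele = s.allele_by_genotype.get(g)
                gt = "0/0" if allele == ref else "1/1" if allele == alt else "./."
                dp = s.depth_by_genotype.get(g, 0)
                samples.append(f"{gt}:{dp}")
            fh.write(
                f"{s.contig_id}\t{s.pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT:DP\t"
                + "\t".join(samples) + "\n"
            )
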