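"""Cross-assembly SNP comparison via 101-nt SNP-centered windows.

Each filtered SNP is represented by the 101-nt fragment of its contig with
the SNP at the center (offset 51, 1-based). Windows from two assemblies
are compared by optimal local alignment; a valid hit needs at least 80
identical aligned bases, and a SNP counts as *common* to both assemblies
only when the best valid hits are reciprocal. A deterministic match-count /
identity criterion replaces heuristic database-search E-values: window
length is fixed at 101 nt, so the operative rule is the 80-base match
count (and a 95% identity cut for the assay-window lookup), which makes
results bit-reproducible and independent of database size. Both
orientations are searched; the better of forward and reverse complement is
taken.

Alignment engine: Biopython's PairwiseAligner in local mode (match +1,
mismatch -2; a gap of length k costs 5 + 2k). Ties among co-optimal
alignments resolve to the aligner's canonical first traceback.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio import Align

from .io_formats import SequenceRecord
from .synthetic_data import revcomp

WINDOW_FLANK = 50
WINDOW_LEN = 2 * WINDOW_FLANK + 1  # 101
DEFAULT_MIN_MATCHES = 80
DEFAULT_MIN_IDENTITY = 0.95


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5   # charged once per gap, on top of per-base extension
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class SNPWindow:
    """A 101-nt SNP-centered fragment (SNP at 1-based offset 51)."""

    snp_id: str
    sequence: str
    contig_id: str = ""
    pos: int = 0  # 1-based SNP position on the source contig

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LEN:
            raise ValueError(
                f"window {self.snp_id!r}: length {len(self.sequence)} != {WINDOW_LEN}")

    @property
    def center_base(self) -> str:
        return self.sequence[WINDOW_FLANK]


@dataclass(frozen=True)
class WindowHit:
    """Best local alignment between a query and subject window."""

    query_id: str
    subject_id: str
    n_matches: int
    n_aligned: int
    score: float
    strand: str = "+"

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_aligned if self.n_aligned else 0.0


def extract_window(contig: SequenceRecord | str, pos: int, snp_id: str | None = None,
                   ) -> SNPWindow:
    """Cut the 101-nt window [pos-50, pos+50] around a 1-based SNP position.

    Raises ValueError when fewer than 50 bases flank the SNP (such SNPs
    should already have been removed by the distance filters).
    """
    if isinstance(contig, SequenceRecord):
        seq, cid = contig.sequence, contig.id
    else:
        seq, cid = contig, ""
    if pos - WINDOW_FLANK < 1 or pos + WINDOW_FLANK > len(seq):
        raise ValueError(
            f"SNP at {cid or '<seq>'}:{pos} has fewer than {WINDOW_FLANK} "
            "flanking bases; filtered SNP sets guarantee full windows")
    return SNPWindow(
        snp_id=snp_id or f"{cid}:{pos}",
        sequence=seq[pos - WINDOW_FLANK - 1: pos + WINDOW_FLANK],
        contig_id=cid, pos=pos)


#: tie-break scale: every score unit is worth _SCALE, every matching column
#: an extra +1, so the engine's optimum is the lexicographic (score, matches)
#: maximum. Valid while the shorter sequence is under _SCALE bases.
_SCALE = 10_000


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = scoring.match * _SCALE + 1
    aln.mismatch_score = scoring.mismatch * _SCALE
    # PairwiseAligner's open score already includes the first extension
    aln.open_gap_score = (scoring.gap_open + scoring.gap_extend) * _SCALE
    aln.extend_gap_score = scoring.gap_extend * _SCALE
    return aln


def local_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
                query_id: str = "", subject_id: str = "") -> WindowHit:
    """Optimal local alignment of two sequences (forward orientation).

    Among score-co-optimal alignments the one with the most matching
    columns is reported (so a full-length alignment is preferred over one
    with score-neutral trimmed ends); remaining ties resolve to the
    engine's canonical traceback.
    """
    if min(len(a), len(b)) >= _SCALE:
        raise ValueError("local_align is limited to sequences < 10 kb")
    aligner = _aligner(scoring)
    alignments = aligner.align(a.upper(), b.upper())
    if len(alignments) == 0 or alignments.score <= 0:
        return WindowHit(query_id, subject_id, 0, 0, 0.0)
    scaled = int(alignments.score)
    score, n_matches = divmod(scaled, _SCALE)
    counts = alignments[0].counts()
    assert int(counts.identities) == n_matches
    return WindowHit(
        query_id, subject_id, n_matches,
        int(counts.gaps + counts.identities + counts.mismatches),
        float(score))


def best_local_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
                     query_id: str = "", subject_id: str = "") -> WindowHit:
    """Better of forward and reverse-complement local alignments.

    Forward wins ties, so same-strand assemblies compare reproducibly.
    """
    fwd = local_align(a, b, scoring, query_id, subject_id)
    rev = local_align(a, revcomp(b), scoring, query_id, subject_id)
    if (rev.score, rev.n_matches) > (fwd.score, fwd.n_matches):
        return WindowHit(query_id, subject_id, rev.n_matches, rev.n_aligned,
                         rev.score, strand="-")
    return fwd


# ---------------------------------------------------------------------------
# reciprocal SNP-set comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Outcome of the reciprocal window comparison of two SNP sets."""

    common: list[tuple[str, str, int]]  # (id_A, id_B, n_matches)
    unique_a: list[str]
    unique_b: list[str]

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)


def _best_hits(queries: Sequence[SNPWindow], subjects: Sequence[SNPWindow],
               min_matches: int, scoring: Scoring) -> dict[str, tuple[str, int]]:
    """Best valid hit per query (max matches; ties -> first subject)."""
    hits: dict[str, tuple[str, int]] = {}
    for q in queries:
        best: tuple[int, int] | None = None  # (-n_matches, subject index)
        for j, s in enumerate(subjects):
            h = best_local_align(q.sequence, s.sequence, scoring)
            if h.n_matches >= min_matches:
                key = (-h.n_matches, j)
                if best is None or key < best:
                    best = key
        if best is not None:
            hits[q.snp_id] = (subjects[best[1]].snp_id, -best[0])
    return hits


def compare_snp_sets(
    windows_a: Sequence[SNPWindow],
    windows_b: Sequence[SNPWindow],
    min_matches: int = DEFAULT_MIN_MATCHES,
    scoring: Scoring = DEFAULT_SCORING,
) -> ComparisonResult:
    """Reciprocal-best-hit partition of two SNP-window sets.

    A SNP in A is common iff its best valid hit (>= min_matches matching
    bases) is some window b in B whose own best valid hit is that same SNP;
    every other SNP is unique to its assembly. common + unique always
    partitions each input set exactly.
    """
    fwd = _best_hits(windows_a, windows_b, min_matches, scoring)
    rev = _best_hits(windows_b, windows_a, min_matches, scoring)
    common = []
    common_a: set[str] = set()
    common_b: set[str] = set()
    for a_id, (b_id, m) in fwd.items():
        if rev.get(b_id, (None,))[0] == a_id:
            common.append((a_id, b_id, m))
            common_a.add(a_id)
            common_b.add(b_id)
    return ComparisonResult(
        common=common,
        unique_a=[w.snp_id for w in windows_a if w.snp_id not in common_a],
        unique_b=[w.snp_id for w in windows_b if w.snp_id not in common_b])


def kaspar_window_lookup(
    window: SNPWindow,
    assembly: Sequence[SequenceRecord] | Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned: int = DEFAULT_MIN_MATCHES,
    scoring: Scoring = DEFAULT_SCORING,
) -> WindowHit | None:
    """Locate an assay window in another assembly.

    Best local alignment of the 101-nt window against every contig (both
    orientations); a hit requires identity >= min_identity over at least
    ``min_aligned`` aligned bases — the deterministic surrogate for a
    similarity + E-value cut in a heuristic search.
    """
    if isinstance(assembly, Mapping):
        items = list(assembly.items())
    else:
        items = [(c.id, c.sequence) for c in assembly]
    best: WindowHit | None = None
    for cid, seq in items:
        h = best_local_align(window.sequence, seq, scoring,
                             query_id=window.snp_id, subject_id=cid)
        if best is None or (h.score, h.n_matches) > (best.score, best.n_matches):
            best = h
    if best is not None and best.n_aligned >= min_aligned \
            and best.identity >= min_identity:
        return best
    return None
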