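"""Microsatellite (SSR) detection, motif canonicalization and primer tasks.

The scanner reports maximal perfect tandem repeats of 2-6 nt motifs that
meet a per-unit-size minimum repeat count (defaults: dinucleotide >= 6
repeats, 3-6 nt motifs >= 5 repeats; mononucleotide runs are not considered
SSR markers here). Nearby SSRs separated by at most a fixed spacer
(default 100 bp) are merged into compound SSRs. Motifs are grouped into
canonical strand/phase-independent classes (e.g. AG/CT), SSRs can be
matched across two assemblies by class, length and flanking-sequence
identity, and each SSR can be turned into a Primer3 (boulder-IO) design
task targeting a 100-300 bp amplicon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord
from .synthetic_data import DEFAULT_SSR_THRESHOLDS, revcomp

DEFAULT_MAX_SPACER = 100


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRRecord:
    """A perfect microsatellite (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    kind: str = "perfect"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_size * self.repeat_count:
            raise ValueError("span must equal unit_size * repeat_count")

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    @property
    def canonical_class(self) -> str:
        return canonical_motif(self.motif)

    def formatted(self) -> str:
        return f"({self.motif}){self.repeat_count}"


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more SSRs separated by spacers of at most max_spacer bases."""

    members: tuple[SSRRecord, ...]
    spacers: tuple[str, ...]  # sequence between consecutive members
    kind: str = "compound"

    def __post_init__(self) -> None:
        if len(self.members) < 2 or len(self.spacers) != len(self.members) - 1:
            raise ValueError("compound SSR needs >= 2 members and n-1 spacers")

    @property
    def contig_id(self) -> str:
        return self.members[0].contig_id

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    def formatted(self) -> str:
        """MISA-style display, spacer sequence lowercased: (AC)6tt(AG)7."""
        parts = [self.members[0].formatted()]
        for spacer, member in zip(self.spacers, self.members[1:]):
            parts.append(spacer.lower())
            parts.append(member.formatted())
        return "".join(parts)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _minimal_period(motif: str) -> int:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n


def find_perfect_ssrs(
    seq: str,
    thresholds: Mapping[int, int] = DEFAULT_SSR_THRESHOLDS,
    contig_id: str = "",
) -> list[SSRRecord]:
    """Find maximal perfect tandem repeats of unit sizes 2-6.

    A run is reported at its leftmost maximal extent, truncated to complete
    repeat units; runs whose motif is itself a tandem of a smaller unit
    (e.g. ATAT as a 4-mer) are reported only at the smallest unit size.
    N breaks every run. Overlapping runs of different (non-reducible) unit
    sizes are each reported. Output is sorted by start, then unit size.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(arr)
    is_n = arr == ord("N")
    out: list[SSRRecord] = []
    for u, min_rep in sorted(thresholds.items()):
        if u < 2 or n < u * min_rep:
            continue
        eq = (arr[u:] == arr[:-u]) & ~is_n[u:]
        # maximal True stretches of eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for a, b in zip(starts, ends):
            span = (b - a) + u
            count = span // u
            if count < min_rep:
                continue
            motif = seq[a:a + u].upper()
            if "N" in motif or _minimal_period(motif) < u:
                continue
            out.append(SSRRecord(
                contig_id=contig_id, start=int(a) + 1,
                end=int(a) + count * u, motif=motif, repeat_count=int(count)))
    out.sort(key=lambda r: (r.start, r.unit_size))
    return out


def merge_compound(
    ssrs: Sequence[SSRRecord],
    max_spacer: int = DEFAULT_MAX_SPACER,
    seq: str | None = None,
) -> tuple[list[SSRRecord], list[CompoundSSR]]:
    """Chain consecutive SSRs whose gap is <= max_spacer into compound SSRs.

    ``ssrs`` must be sorted by start and belong to one contig. Each input
    SSR ends up in exactly one output record. When ``seq`` is supplied the
    compound's spacer sequences are taken from it; otherwise they are
    rendered as 'n' placeholders of the right length.
    """
    perfect: list[SSRRecord] = []
    compounds: list[CompoundSSR] = []
    chain: list[SSRRecord] = []

    def flush() -> None:
        if len(chain) == 1:
            perfect.append(chain[0])
        elif len(chain) > 1:
            spacers = []
            for prev, nxt in zip(chain, chain[1:]):
                gap = nxt.start - prev.end - 1
                spacers.append(seq[prev.end:nxt.start - 1] if seq is not None
                               else "n" * gap)
            compounds.append(CompoundSSR(tuple(chain), tuple(spacers)))
        chain.clear()

    for rec in ssrs:
        if chain and rec.start - chain[-1].end - 1 <= max_spacer:
            chain.append(rec)
        else:
            flush()
            chain.append(rec)
    flush()
    return perfect, compounds


# ---------------------------------------------------------------------------
# canonical motif classes
# ---------------------------------------------------------------------------

def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonical_motif(motif: str) -> str:
    """Canonical strand/phase-independent class label of a motif.

    The representative is the lexicographically smallest string among all
    rotations of the motif and all rotations of its reverse complement; the
    printed partner is the smallest rotation of the representative's reverse
    complement other than the representative itself (so palindromic-class
    motifs like AT still print a two-sided label, AT/TA). Labels follow the
    field's convention: AG/CT, AAC/GTT, AT/TA.
    """
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be non-empty over ACGT: {motif!r}")
    pool = _rotations(motif) + _rotations(revcomp(motif))
    rep = min(pool)
    partner_pool = [r for r in _rotations(revcomp(rep)) if r != rep]
    partner = min(partner_pool) if partner_pool else rep
    return f"{rep}/{partner}"


# ---------------------------------------------------------------------------
# cross-assembly SSR matching
# ---------------------------------------------------------------------------

def ssr_window(rec: SSRRecord | CompoundSSR, seq: str, flank: int = 50) -> str:
    """SSR span plus up to ``flank`` bases of context on each side."""
    lo = max(0, rec.start - 1 - flank)
    hi = min(len(seq), rec.end + flank)
    return seq[lo:hi]


def match_ssrs_across_assemblies(
    ssrs_a: Sequence[SSRRecord],
    contigs_a: Mapping[str, str] | Sequence[SequenceRecord],
    ssrs_b: Sequence[SSRRecord],
    contigs_b: Mapping[str, str] | Sequence[SequenceRecord],
    flank: int = 50,
    min_matches: int = 80,
) -> list[tuple[SSRRecord, SSRRecord, int]]:
    """Greedy best-hit pairing of SSRs common to two assemblies.

    A pair is common iff canonical class and repeat count are identical and
    the flanking windows align with at least ``min_matches`` matching bases
    (same alignment engine as the SNP-window comparison, both orientations).
    Each SSR is matched at most once; pairs are taken best-match-first.
    """
    from .marker_compare import best_local_align

    def as_map(contigs):
        if isinstance(contigs, Mapping):
            return dict(contigs)
        return {c.id: c.sequence for c in contigs}

    seq_a, seq_b = as_map(contigs_a), as_map(contigs_b)
    by_key: dict[tuple[str, int], list[int]] = {}
    for j, sb in enumerate(ssrs_b):
        by_key.setdefault((sb.canonical_class, sb.repeat_count), []).append(j)

    scored: list[tuple[int, int, int]] = []  # (n_matches, i, j)
    for i, sa in enumerate(ssrs_a):
        cands = by_key.get((sa.canonical_class, sa.repeat_count), [])
        if not cands:
            continue
        wa = ssr_window(sa, seq_a[sa.contig_id], flank)
        for j in cands:
            sb = ssrs_b[j]
            wb = ssr_window(sb, seq_b[sb.contig_id], flank)
            hit = best_local_align(wa, wb)
            if hit.n_matches >= min_matches:
                scored.append((hit.n_matches, i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for m, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((ssrs_a[i], ssrs_b[j], m))
    return pairs


# ---------------------------------------------------------------------------
# Primer3 task generation / output parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPolicy:
    product_size_range: tuple[int, int] = (100, 300)
    optimal_tm: float = 60.0
    optimal_primer_len: int = 20


@dataclass(frozen=True)
class PrimerTask:
    """A Primer3 design task targeting one SSR span within its contig.

    ``target`` is (1-based start, length) of the SSR within the template;
    ``edge_warning`` marks SSRs flush against a contig end, where flanking
    primers may not be designable.
    """

    seq_id: str
    template: str
    target: tuple[int, int]
    policy: PrimerPolicy = PrimerPolicy()
    edge_warning: bool = False

    def to_boulder(self) -> str:
        lines = [
            f"SEQUENCE_ID={self.seq_id}",
            f"SEQUENCE_TEMPLATE={self.template}",
            f"SEQUENCE_TARGET={self.target[0]},{self.target[1]}",
            "PRIMER_PRODUCT_SIZE_RANGE="
            f"{self.policy.product_size_range[0]}-{self.policy.product_size_range[1]}",
            f"PRIMER_OPT_TM={self.policy.optimal_tm:g}",
            f"PRIMER_OPT_SIZE={self.policy.optimal_primer_len}",
            "=",
        ]
        return "\n".join(lines) + "\n"


def make_primer3_input(
    rec: SSRRecord | CompoundSSR,
    contig: SequenceRecord,
    policy: PrimerPolicy = PrimerPolicy(),
) -> PrimerTask:
    """Build a boulder-IO design task for one SSR (flanks required).

    The target span is the SSR itself; an SSR flush against either contig
    end gets ``edge_warning=True`` (task still emitted).
    """
    if rec.start < 1 or rec.end > len(contig):
        raise ValueError(f"SSR span outside contig {contig.id!r}")
    edge = rec.start <= 1 or rec.end >= len(contig)
    seq_id = f"{contig.id}_{rec.start}"
    return PrimerTask(
        seq_id=seq_id, template=contig.sequence,
        target=(rec.start, rec.end - rec.start + 1),
        policy=policy, edge_warning=edge)


def parse_primer3_output(text: str) -> dict[str, list[dict[str, object]]]:
    """Parse Primer3 boulder-IO output into primer pairs keyed by seq id.

    Recognizes PRIMER_{LEFT,RIGHT}_<i>_SEQUENCE, their TM tags and
    PRIMER_PAIR_<i>_PRODUCT_SIZE.
    """
    out: dict[str, list[dict[str, object]]] = {}
    record: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if line == "=":
            _flush_primer_record(record, out)
            record = {}
            continue
        if "=" in line:
            k, v = line.split("=", 1)
            record[k] = v
    if record:
        _flush_primer_record(record, out)
    return out


def _flush_primer_record(record: dict[str, str],
                         out: dict[str, list[dict[str, object]]]) -> None:
    if not record:
        return
    seq_id = record.get("SEQUENCE_ID", "")
    pairs = []
    i = 0
    while f"PRIMER_LEFT_{i}_SEQUENCE" in record:
        pair: dict[str, object] = {
            "left": record[f"PRIMER_LEFT_{i}_SEQUENCE"],
            "right": record.get(f"PRIMER_RIGHT_{i}_SEQUENCE", ""),
        }
        if f"PRIMER_LEFT_{i}_TM" in record:
            pair["left_tm"] = float(record[f"PRIMER_LEFT_{i}_TM"])
        if f"PRIMER_RIGHT_{i}_TM" in record:
            pair["right_tm"] = float(record[f"PRIMER_RIGHT_{i}_TM"])
        if f"PRIMER_PAIR_{i}_PRODUCT_SIZE" in record:
            pair["product_size"] = int(record[f"PRIMER_PAIR_{i}_PRODUCT_SIZE"])
        pairs.append(pair)
        i += 1
    out[seq_id] = pairs


# ---------------------------------------------------------------------------
# MISA-shaped table
# ---------------------------------------------------------------------------

def ssr_frame(perfect: Sequence[SSRRecord],
              compounds: Sequence[CompoundSSR] = ()) -> pd.DataFrame:
    """Tabulate SSRs in a MISA-like layout plus the canonical class."""
    rows = []
    nr = 0
    for rec in sorted(list(perfect) + list(compounds),
                      key=lambda r: (r.contig_id, r.start)):
        nr += 1
        if isinstance(rec, SSRRecord):
            ssr_type = f"p{rec.unit_size}"
            cclass = rec.canonical_class
        else:
            ssr_type = "c"
            cclass = ";".join(m.canonical_class for m in rec.members)
        rows.append({
            "ID": rec.contig_id, "SSR nr.": nr, "SSR type": ssr_type,
            "SSR": rec.formatted(), "size": rec.end - rec.start + 1,
            "start": rec.start, "end": rec.end, "canonical_class": cclass,
        })
    return pd.DataFrame(rows)
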