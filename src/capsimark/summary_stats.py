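"""Assembly and marker summary statistics.

N50 is the standard length-weighted median: the length L such that contigs
of length >= L contain at least half of the assembled bases. GC% excludes
N from the denominator. Size-bin edges follow the conventional report
layout (<1 KB, 1-2, 2-3, 3-4, 4-5, 5-10, 10-20 KB, plus an overflow bin).
All reported figures are rounded half-up at their printed precision via a
single shared helper, so e.g. 113/126 prints 89.7 and 11,847,000 bases per
4,234 markers prints 2,798 bases per marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .io_formats import SequenceRecord

SIZE_BIN_EDGES = [1_000, 2_000, 3_000, 4_000, 5_000, 10_000, 20_000]
SIZE_BIN_LABELS = ["<1KB", "1-2KB", "2-3KB", "3-4KB", "4-5KB",
                   "5-10KB", "10-20KB", ">=20KB"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the reported precision (3.5 -> 4)."""
    q = Decimal(1).scaleb(-decimals)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v if decimals > 0 else int(v) if abs(v) < 2**53 else v


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_nt: int
    gc_pct: float         # one decimal
    longest: int
    mean_len: float       # one decimal
    median_len: float
    n50: int
    size_bins: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Number of Unigenes", self.n_contigs),
            ("Total assembled nucleotides", self.total_nt),
            ("Average GC content (%)", self.gc_pct),
            ("Longest Contig Length", self.longest),
            ("Average Contig Length", self.mean_len),
            ("Median Contig Length", self.median_len),
            ("N50", self.n50),
        ] + [(f"Contigs {label}", n) for label, n in self.size_bins.items()]
        return pd.DataFrame(rows, columns=["Statistic", "Value"])


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L (taken from the set) such that contigs >= L hold
    at least half the total bases: sort descending, accumulate."""
    if not lengths:
        raise ValueError("N50 of an empty assembly is undefined")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


def gc_percent(seqs: Sequence[str], decimals: int = 1) -> float:
    """(G+C)/(A+C+G+T) x 100; N excluded from the denominator."""
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    acgt = sum(len(s) - s.count("N") for s in seqs)
    if acgt == 0:
        raise ValueError("no A/C/G/T bases")
    return round_half_up(100.0 * gc / acgt, decimals)


def assembly_stats(contigs: Sequence[SequenceRecord]) -> AssemblyStats:
    """Table-style summary of an assembly (>= 1 contig required)."""
    if not contigs:
        raise ValueError("empty assembly")
    lengths = [len(c) for c in contigs]
    seqs = [c.sequence for c in contigs]
    total = sum(lengths)
    bins = {label: 0 for label in SIZE_BIN_LABELS}
    for L in lengths:
        for edge, label in zip(SIZE_BIN_EDGES, SIZE_BIN_LABELS):
            if L < edge:
                bins[label] += 1
                break
        else:
            bins[SIZE_BIN_LABELS[-1]] += 1
    med = sorted(lengths)[len(lengths) // 2] if len(lengths) % 2 else (
        sum(sorted(lengths)[len(lengths) // 2 - 1: len(lengths) // 2 + 1]) / 2)
    return AssemblyStats(
        n_contigs=len(contigs),
        total_nt=total,
        gc_pct=gc_percent(seqs),
        longest=max(lengths),
        mean_len=round_half_up(total / len(lengths), 1),
        median_len=med,
        n50=n50(lengths),
        size_bins=bins,
    )


@dataclass(frozen=True)
class DensityStat:
    total_bases: int
    n_markers: int
    bases_per_marker: int | None        # nearest integer; None when no markers
    markers_per_contig: float | None    # one decimal, when contig count known


def snp_density(total_bases: int, n_markers: int,
                n_contigs: int | None = None) -> DensityStat:
    """Average spacing of markers: bases per marker, rounded to the integer.

    With zero markers the density is undefined and reported as NA (None).
    """
    if n_markers == 0:
        return DensityStat(total_bases, 0, None, None)
    bpm = int(round_half_up(total_bases / n_markers, 0))
    mpc = round_half_up(n_markers / n_contigs, 1) if n_contigs else None
    return DensityStat(total_bases, n_markers, bpm, mpc)


def rate_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 x num/den, rounded half-up to ``decimals``."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    return round_half_up(100.0 * numerator / denominator, decimals)
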