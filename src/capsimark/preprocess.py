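"""Read trimming.

Two policies are implemented, mirroring a two-tier short-read cleanup used
ahead of de Bruijn assembly of 85-cycle reads:

* **normal** — strip low-quality bases (Phred < 20, i.e. error probability
  above 0.01) from both ends, then retain reads of 40-85 nt;
* **stringent** — applied to reads that already passed the normal policy:
  cut a fixed 10 nt from the 5' end and 5 nt from the 3' end, retaining
  reads of 25-70 nt.

Quality trimming is a simple end-strip loop: bases are removed from either
end while the terminal base is below the threshold. Adapter removal is out
of scope here; reads are assumed adapter-clean (a pass-through hook lets an
external adapter trimmer run first).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import pandas as pd

from .io_formats import QualityRead


@dataclass(frozen=True)
class TrimPolicy:
    qual_threshold: int = 20
    min_len: int = 40
    max_len: int = 85
    head_trim: int = 0
    tail_trim: int = 0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.head_trim < 0 or self.tail_trim < 0:
            raise ValueError("fixed trims must be >= 0")


#: Full-filtered-length policy: Q20 end strip, keep 40-85 nt.
NORMAL_POLICY = TrimPolicy(qual_threshold=20, min_len=40, max_len=85)
#: Stringent policy: fixed 10 nt / 5 nt end cuts on normal-policy output, keep 25-70 nt.
STRINGENT_POLICY = TrimPolicy(qual_threshold=20, min_len=25, max_len=70,
                              head_trim=10, tail_trim=5)


def quality_trim(read: QualityRead, policy: TrimPolicy = NORMAL_POLICY) -> QualityRead | None:
    """End-strip bases with Phred below the threshold; None if length falls
    outside [min_len, max_len]."""
    lo, hi = 0, len(read)
    while lo < hi and read.quals[lo] < policy.qual_threshold:
        lo += 1
    while hi > lo and read.quals[hi - 1] < policy.qual_threshold:
        hi -= 1
    n = hi - lo
    if n < policy.min_len or n > policy.max_len:
        return None
    if lo == 0 and hi == len(read):
        return read
    return QualityRead(read.id, read.sequence[lo:hi], read.quals[lo:hi])


def stringent_trim(read: QualityRead, policy: TrimPolicy = STRINGENT_POLICY) -> QualityRead | None:
    """Cut fixed head/tail lengths from a quality-trimmed read; None if the
    result falls outside [min_len, max_len]."""
    lo = policy.head_trim
    hi = len(read) - policy.tail_trim
    n = hi - lo
    if n < policy.min_len or n > policy.max_len:
        return None
    return QualityRead(read.id, read.sequence[lo:hi], read.quals[lo:hi])


@dataclass
class TrimReport:
    """Input/retained counts plus a retained-length histogram."""

    n_input: int = 0
    n_retained: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_retained

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_input", self.n_input), ("n_retained", self.n_retained),
                ("n_rejected", self.n_rejected)]
        rows += [(f"len_{k}", v) for k, v in sorted(self.length_histogram.items())]
        return pd.DataFrame(rows, columns=["metric", "value"])


def trim_stream(
    reads: Iterable[QualityRead],
    policy_name: str = "normal",
    report: TrimReport | None = None,
    adapter_hook: Callable[[QualityRead], QualityRead] | None = None,
) -> Iterator[QualityRead]:
    """Apply a named trimming policy ('normal' or 'stringent') to a stream.

    The stringent policy composes both steps: Q20 end strip at 40-85 nt, then
    the fixed 10/5 cuts at 25-70 nt. ``adapter_hook`` may pre-clean each read.
    """
    if policy_name not in ("normal", "stringent"):
        raise ValueError(f"unknown trim policy {policy_name!r}")
    for read in reads:
        if report is not None:
            report.n_input += 1
        if adapter_hook is not None:
            read = adapter_hook(read)
        trimmed = quality_trim(read, NORMAL_POLICY)
        if trimmed is not None and policy_name == "stringent":
            trimmed = stringent_trim(trimmed, STRINGENT_POLICY)
        if trimmed is None:
            continue
        if report is not None:
            report.n_retained += 1
            report.length_histogram[len(trimmed)] += 1
        yield trimmed
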