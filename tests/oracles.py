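"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles, by a
different route than the implementation under test: per-start tandem
enumeration for SSRs, a plain Gotoh dynamic program for local alignment,
all-position Hamming scan for read placement, and definitional N50.
"""

from __future__ import annotations


def minimal_period(motif: str) -> int:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n


def brute_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple[int, int, int]]:
    """All maximal perfect tandem runs as (1-based start, unit, count).

    Per unit size, every start position is tried; a start inside an
    already-seen run (a shifted frame of the same tandem) is shadowed.
    Reducible motifs (tandems of a smaller unit) are not reported at the
    larger unit size. N breaks runs.
    """
    seq = seq.upper()
    n = len(seq)
    out: set[tuple[int, int, int]] = set()
    for u, min_rep in thresholds.items():
        covered_until = 0
        for i in range(0, n - u + 1):
            if i < covered_until:
                continue
            motif = seq[i:i + u]
            if "N" in motif:
                continue
            count = 1
            while i + (count + 1) * u <= n and \
                    seq[i + count * u: i + (count + 1) * u] == motif:
                count += 1
            # partial extension of the repeat structure past complete units
            e = i + count * u
            while e < n and seq[e] != "N" and seq[e] == seq[e - u]:
                e += 1
            if e > i + u:  # a genuine tandem structure begins at i
                # starts up to e-u are shifted frames of this same run; the
                # next maximal run can begin no earlier than e-u+1
                covered_until = e - u + 1
                if count >= min_rep and minimal_period(motif) == u:
                    out.add((i + 1, u, count))
    return out


def sw_score(a: str, b: str, match: int = 1, mismatch: int = -2,
             gap_open: int = -5, gap_extend: int = -2) -> int:
    """Optimal local-alignment (Gotoh) score; length-k gap costs open+k*ext."""
    la, lb = len(a), len(b)
    NEG = -10 ** 9
    first = gap_open + gap_extend
    h_prev = [0] * (lb + 1)
    e_prev = [NEG] * (lb + 1)
    best = 0
    for i in range(1, la + 1):
        h_cur = [0] * (lb + 1)
        e_cur = [NEG] * (lb + 1)
        f = NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e_cur[j] = max(h_prev[j] + first, e_prev[j] + gap_extend)
            f = max(h_cur[j - 1] + first, f + gap_extend)
            sub = h_prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            h = max(0, sub, e_cur[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best


def hamming_scan(read: str, contigs: dict[str, str]) -> list[tuple[str, int, int]]:
    """All placements attaining the minimum Hamming distance.

    Returns (contig_id, 1-based pos, mismatches) for every best placement.
    """
    n = len(read)
    best = n + 1
    hits: list[tuple[str, int, int]] = []
    for cid, seq in contigs.items():
        for p in range(0, len(seq) - n + 1):
            mm = sum(x != y for x, y in zip(read, seq[p:p + n]))
            if mm < best:
                best = mm
                hits = [(cid, p + 1, mm)]
            elif mm == best:
                hits.append((cid, p + 1, mm))
    return hits


def n50_definitional(lengths: list[int]) -> int:
    """Largest length L in the multiset with sum(x >= L) >= half the total."""
    total = sum(lengths)
    candidates = [L for L in set(lengths)
                  if 2 * sum(x for x in lengths if x >= L) >= total]
    return max(candidates)
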