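"""Synthetic transcriptome generator with planted ground truth.

Emulates the data structure of a three-line inbred-pepper transcriptome
experiment: a set of multi-exon transcript contigs (the consensus assembly),
three near-isogenic homozygous genotypes differing at planted biallelic
SNPs, occasional residual heterozygous positions, planted microsatellites,
exon-exon junction coordinates, and 85-nt reads with Phred-scored
substitution errors. Every downstream stage (trimming, mapping, pileup
genotyping, SNP filtering, SSR scanning) is testable against the returned
:class:`TruthSet` without any external download.

Planted SNPs are divided into *clean* sites that respect every 50-bp
distance filter and deliberate *violators* (near a junction, adjacent SNP
pairs, or next to a heterozygous site) so the filters themselves can be
exercised.

Coverage design: read start positions are stratified-uniform (one start
drawn uniformly inside each of ``n_reads`` equal-width intervals along the
transcript). Marginally every start is uniform, but the per-site depth is
tightly concentrated around the configured mean, so genotype-call recovery
measures the caller rather than coverage luck. At planted heterozygous
sites the two alleles alternate read-by-read — an exact 50/50 draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    JunctionSet,
    QualityRead,
    SequenceRecord,
    write_fasta,
    write_fastq,
    write_junction_tsv,
)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Minimum repeat count per SSR motif unit size (unit size -> min repeats).
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: Motifs offered to the SSR planter (non-reducible, mixed unit sizes).
_PLANT_MOTIFS = ("AC", "AG", "AT", "CT", "GT",
                 "AAC", "AAG", "AAT", "ACC", "AGG", "ATC",
                 "AAAC", "AAGG", "ACAT", "AGAT")

#: Features closer than this to a contig end are never planted; keeps the
#: planted sites inside the flat-coverage interior of the read layout and
#: leaves room for 101-nt marker windows.
_EDGE_MARGIN = 150
#: Spacing of candidate planting anchors; > 2x the 50-bp filter radius so
#: distinct features never interact.
_ANCHOR_SPACING = 130


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulated experiment.

    Rates are per kilobase of transcript unless noted. Defaults follow the
    emulated experiment: three homozygous pepper lines, 85-nt reads, SNP
    density near one per 2.5 kb, and a mean per-line depth of 20.
    """

    n_genes: int = 40
    transcript_len: tuple[int, int] = (1500, 2500)
    n_exons: tuple[int, int] = (1, 8)
    genotype_names: tuple[str, ...] = ("CM334", "Maor", "EJ")
    snp_rate: float = 0.4          # planted SNPs per kb (~1 per 2.5 kb)
    het_rate: float = 0.1          # isolated residual heterozygous sites per kb
    violator_fraction: float = 0.25  # fraction of SNPs planted to violate a filter
    ssr_plant_rate: float = 0.1    # planted SSRs per transcript
    read_len: int = 85
    depth_per_line: float = 20.0
    error_rate: float = 0.005
    qual_mean: tuple[float, float] = (38.0, 30.0)  # mean Phred at 5' / 3' end
    qual_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.snp_rate, self.het_rate, self.ssr_plant_rate,
               self.error_rate, self.depth_per_line) < 0:
            raise ValueError("rates must be >= 0")
        if self.read_len < 25:
            raise ValueError("read_len must be >= 25")
        if len(self.genotype_names) < 3:
            raise ValueError("at least 3 genotype names are required "
                             "for the 2-of-3 caller")
        if not (0 <= self.violator_fraction <= 1):
            raise ValueError("violator_fraction must be in [0, 1]")

    @classmethod
    def from_flat(cls, d: Mapping[str, object]) -> "SimConfig":
        """Build from a flat key-value mapping (config-file friendly).

        Pair fields accept ``"lo,hi"`` strings or 2-sequences; the genotype
        list accepts a comma-separated string.
        """
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in d.items():
            if key not in fields:
                raise KeyError(f"unknown simulation key {key!r}")
            if key in ("transcript_len", "n_exons", "qual_mean"):
                if isinstance(val, str):
                    val = val.split(",")
                lo, hi = val
                cast = float if key == "qual_mean" else int
                kwargs[key] = (cast(lo), cast(hi))
            elif key == "genotype_names":
                if isinstance(val, str):
                    val = val.split(",")
                kwargs[key] = tuple(str(v).strip() for v in val)
            else:
                cast = type(fields[key].default)
                kwargs[key] = cast(val)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    """One planted polymorphic site (1-based position on the contig).

    ``alleles`` maps genotype name to its allele; a heterozygous genotype is
    written ``"X/Y"``. ``kind`` records why the site was planted: ``clean``
    sites respect every distance filter; ``near_junction``, ``adjacent_pair``
    and ``near_het`` SNPs each violate one; ``het_site`` / ``het_companion``
    are heterozygous positions (the latter planted next to a near_het SNP).
    """

    contig_id: str
    pos: int
    alleles: dict[str, str]
    is_het: bool
    kind: str

    @property
    def is_snp(self) -> bool:
        return not self.is_het


@dataclass(frozen=True)
class PlantedSSR:
    contig_id: str
    start: int  # 1-based
    motif: str
    count: int

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.count - 1


@dataclass
class TruthSet:
    """Simulated contigs plus every planted feature, for recovery tests."""

    config: SimConfig
    contigs: list[SequenceRecord]
    junctions: JunctionSet
    variants: list[PlantedVariant]
    ssrs: list[PlantedSSR]
    #: per-genotype homozygous haplotype sequence per contig (het sites carry
    #: the consensus allele here; the read simulator alternates alleles).
    haplotypes: dict[str, dict[str, str]]

    def contig_lengths(self) -> dict[str, int]:
        return {c.id: len(c) for c in self.contigs}

    def snps(self, kinds: Iterable[str] | None = None) -> list[PlantedVariant]:
        sel = [v for v in self.variants if v.is_snp]
        if kinds is not None:
            kinds = set(kinds)
            sel = [v for v in sel if v.kind in kinds]
        return sel

    def het_positions(self) -> list[PlantedVariant]:
        return [v for v in self.variants if v.is_het]


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _exon_lengths(rng: np.random.Generator, total: int, lo: int, hi: int) -> list[int]:
    """Split ``total`` into between lo and hi exons, each >= 60 nt."""
    n_max = min(hi, max(lo, total // 60))
    n = int(rng.integers(lo, n_max + 1)) if n_max > lo else lo
    if n == 1:
        return [total]
    # Draw cut points keeping every exon >= 60 nt: choose n-1 cuts in the
    # "slack" space then re-inflate.
    slack = total - 60 * n
    inner = np.sort(rng.integers(0, slack + 1, size=n - 1))
    lengths = []
    prev = 0
    for i, c in enumerate(inner):
        lengths.append(60 + int(c) - prev)
        prev = int(c)
    lengths.append(60 + slack - prev)
    assert sum(lengths) == total and min(lengths) >= 60
    return lengths


def _plant_ssr(seq: np.ndarray, start0: int, motif: str, count: int) -> None:
    """Write motif^count into seq at 0-based start0 with maximality guards."""
    u = len(motif)
    unit = np.frombuffer(motif.encode(), dtype=np.uint8)
    codes = np.empty(u, dtype=np.int8)
    for i, b in enumerate(motif):
        codes[i] = BASES.index(b)
    span = np.tile(codes, count)
    seq[start0:start0 + u * count] = span
    # guard against accidental left/right extension of the tandem run
    if start0 > 0 and seq[start0 - 1] == seq[start0 - 1 + u]:
        seq[start0 - 1] = (seq[start0 - 1 + u] + 1) % 4
    end = start0 + u * count
    if end < len(seq) and seq[end] == seq[end - u]:
        seq[end] = (seq[end - u] + 1) % 4


def simulate_truth(config: SimConfig) -> TruthSet:
    """Generate contigs, junctions, planted variants and SSRs.

    Deterministic for a fixed seed: a single RNG stream is consumed in
    documented order (per gene: length, exon structure, sequence, SSRs,
    variant plan, variant placement).

    Raises ValueError for infeasible geometry (transcripts too short to hold
    the edge margins plus a requested SSR).
    """
    rng = np.random.default_rng(config.seed)
    lo_len, hi_len = config.transcript_len
    if lo_len < 2 * _EDGE_MARGIN + 100:
        raise ValueError(
            f"transcript_len minimum {lo_len} too short: features need a "
            f"{_EDGE_MARGIN}-nt margin at both ends"
        )
    contigs: list[SequenceRecord] = []
    junctions = JunctionSet()
    variants: list[PlantedVariant] = []
    ssrs: list[PlantedSSR] = []
    genotypes = config.genotype_names
    hap_arrays: dict[str, dict[str, np.ndarray]] = {g: {} for g in genotypes}

    for gi in range(config.n_genes):
        cid = f"contig{gi + 1:04d}"
        L = int(rng.integers(lo_len, hi_len + 1))
        exons = _exon_lengths(rng, L, *config.n_exons)
        jx = list(np.cumsum(exons)[:-1])  # 1-based last-base-of-exon coords
        for j in jx:
            junctions.add(cid, int(j))
        seq = _random_seq(rng, L)

        # ---- anchors: well-spaced interior positions, far enough from
        # junctions (>=110) that a junction-violating SNP planted within
        # 45 nt of a junction still sits >=50 nt from every anchor feature
        anchors = list(range(_EDGE_MARGIN, L - _EDGE_MARGIN, _ANCHOR_SPACING))
        clear_anchors = [a for a in anchors
                        if all(abs(a - j) >= 110 for j in jx)]
        rng.shuffle(clear_anchors)  # type: ignore[arg-type]

        # ---- SSRs first (spans must not overlap variants)
        n_ssr = int(rng.poisson(config.ssr_plant_rate))
        for _ in range(n_ssr):
            if not clear_anchors:
                break
            a = clear_anchors.pop()
            motif = _PLANT_MOTIFS[int(rng.integers(0, len(_PLANT_MOTIFS)))]
            u = len(motif)
            min_rep = DEFAULT_SSR_THRESHOLDS[u]
            count = int(rng.integers(min_rep, min_rep + 5))
            if a + u * count + 1 >= L - _EDGE_MARGIN + _ANCHOR_SPACING:
                continue  # infeasible at this anchor; skip rather than crowd the end
            _plant_ssr(seq, a, motif, count)
            ssrs.append(PlantedSSR(cid, a + 1, motif, count))

        # ---- variant plan
        lam_snp = config.snp_rate * L / 1000.0
        n_snp = int(rng.poisson(lam_snp))
        n_viol = int(round(n_snp * config.violator_fraction))
        n_clean = n_snp - n_viol
        n_het = int(rng.poisson(config.het_rate * L / 1000.0))

        used_pos0: set[int] = set()

        def plant_snp(pos0: int, kind: str) -> None:
            if pos0 in used_pos0:
                return
            used_pos0.add(pos0)
            odd = genotypes[int(rng.integers(0, len(genotypes)))]
            ref = int(seq[pos0])
            alt = int((ref + 1 + rng.integers(0, 3)) % 4)
            alleles = {g: BASES[alt] if g == odd else BASES[ref] for g in genotypes}
            variants.append(PlantedVariant(cid, pos0 + 1, alleles, False, kind))
            _pending_alts.append((odd, cid, pos0, alt))

        def plant_het(pos0: int, kind: str) -> None:
            if pos0 in used_pos0:
                return
            used_pos0.add(pos0)
            g_het = genotypes[int(rng.integers(0, len(genotypes)))]
            ref = int(seq[pos0])
            alt = int((ref + 1 + rng.integers(0, 3)) % 4)
            alleles = {g: f"{BASES[ref]}/{BASES[alt]}" if g == g_het else BASES[ref]
                       for g in genotypes}
            variants.append(PlantedVariant(cid, pos0 + 1, alleles, True, kind))

        _pending_alts: list[tuple[str, str, int, int]] = []

        for _ in range(n_clean):
            if not clear_anchors:
                break
            plant_snp(clear_anchors.pop(), "clean")
        # violators, cycling through the three violation kinds
        viol_kinds = ["near_junction", "adjacent_pair", "near_het"]
        vk = int(rng.integers(0, 3))
        planted_viol = 0
        near_jx_used: set[int] = set()
        while planted_viol < n_viol:
            kind = viol_kinds[vk % 3]
            vk += 1
            if kind == "near_junction":
                candidates = [j for j in jx
                              if _EDGE_MARGIN <= j <= L - _EDGE_MARGIN
                              and j not in near_jx_used]
                if not candidates:
                    planted_viol += 1
                    continue
                j = candidates[int(rng.integers(0, len(candidates)))]
                near_jx_used.add(j)
                off = int(rng.integers(5, 46)) * (1 if rng.random() < 0.5 else -1)
                plant_snp(j - 1 + off, "near_junction")
            elif kind == "adjacent_pair":
                if not clear_anchors:
                    planted_viol += 1
                    continue
                a = clear_anchors.pop()
                d = int(rng.integers(10, 46))
                plant_snp(a, "adjacent_pair")
                plant_snp(a + d, "adjacent_pair")
            else:  # near_het
                if not clear_anchors:
                    planted_viol += 1
                    continue
                a = clear_anchors.pop()
                d = int(rng.integers(10, 46))
                plant_snp(a, "near_het")
                plant_het(a + d, "het_companion")
            planted_viol += 1

        for _ in range(n_het):
            if not clear_anchors:
                break
            plant_het(clear_anchors.pop(), "het_site")

        contig_seq = "".join(BASES[b] for b in seq)
        contigs.append(SequenceRecord(id=cid, sequence=contig_seq))
        for g in genotypes:
            hap = seq.copy()
            for (gg, cc, pos0, alt) in _pending_alts:
                if gg == g:
                    hap[pos0] = alt
            hap_arrays[g][cid] = hap

    haplotypes = {
        g: {cid: "".join(BASES[b] for b in arr) for cid, arr in per.items()}
        for g, per in hap_arrays.items()
    }
    return TruthSet(config=config, contigs=contigs, junctions=junctions,
                    variants=variants, ssrs=ssrs, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(truth: TruthSet, config: SimConfig | None = None,
                   ) -> dict[str, list[QualityRead]]:
    """Simulate single-end sense-strand reads per genotype.

    Start positions are stratified-uniform along each haplotype transcript;
    substitution errors occur at ``error_rate`` per base; quality strings
    follow a linear positional Phred decay. Planted heterozygous sites
    alternate alleles read-by-read (exact 50/50).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_len
    qmean = np.linspace(config.qual_mean[0], config.qual_mean[1], rl)
    reads: dict[str, list[QualityRead]] = {g: [] for g in config.genotype_names}

    het_by_gc: dict[tuple[str, str], list[tuple[int, str, str]]] = {}
    for v in truth.het_positions():
        for g, allele in v.alleles.items():
            if "/" in allele:
                a0, a1 = allele.split("/")
                het_by_gc.setdefault((g, v.contig_id), []).append((v.pos - 1, a0, a1))

    for g in config.genotype_names:
        for contig in truth.contigs:
            cid = contig.id
            hap = truth.haplotypes[g][cid]
            L = len(hap)
            if L < rl or config.depth_per_line <= 0:
                continue
            n_reads = int(round(config.depth_per_line * L / rl))
            if n_reads == 0:
                continue
            # stratified-uniform starts over [0, L - rl]
            edges = np.linspace(0, L - rl + 1, n_reads + 1)
            starts = (edges[:-1]
                      + rng.random(n_reads) * np.diff(edges)).astype(np.int64)
            het_sites = het_by_gc.get((g, cid), [])
            toggles = {pos0: 0 for pos0, _, _ in het_sites}
            for serial, s0 in enumerate(starts):
                s0 = int(s0)
                seq = hap[s0:s0 + rl]
                for pos0, a0, a1 in het_sites:
                    if s0 <= pos0 < s0 + rl:
                        allele = (a0, a1)[toggles[pos0] % 2]
                        toggles[pos0] += 1
                        i = pos0 - s0
                        seq = seq[:i] + allele + seq[i + 1:]
                if config.error_rate > 0:
                    n_err = rng.binomial(rl, config.error_rate)
                    if n_err:
                        epos = rng.choice(rl, size=n_err, replace=False)
                        sl = list(seq)
                        for i in epos:
                            cur = BASES.index(sl[i]) if sl[i] in BASES else 0
                            sl[i] = BASES[(cur + 1 + int(rng.integers(0, 3))) % 4]
                        seq = "".join(sl)
                quals = np.clip(
                    np.rint(qmean + rng.normal(0.0, config.qual_sd, rl)),
                    2, 40).astype(int)
                reads[g].append(QualityRead(
                    id=f"{g}|{cid}|{s0 + 1}|{serial}",
                    sequence=seq, quals=tuple(int(q) for q in quals)))
    return reads


# ---------------------------------------------------------------------------
# naive mapper
# ---------------------------------------------------------------------------

@dataclass
class MapStats:
    placed: int = 0
    ambiguous: int = 0
    unmapped: int = 0


def _hamming(a: str, b: str) -> int:
    if a == b:
        return 0
    return sum(x != y for x, y in zip(a, b))


def naive_map(
    reads: Iterable[QualityRead],
    contigs: Sequence[SequenceRecord],
    genotype_tag: str,
    k: int = 21,
    max_mismatch_frac: float = 0.15,
    stats: MapStats | None = None,
) -> list[AlignmentRecord]:
    """Ungapped end-to-end placement at the unique Hamming-best seeded spot.

    Contigs are indexed by exact k-mers; each read contributes seeds at
    staggered offsets, candidate placements are verified over the full read,
    and the read is kept only when a single placement attains the minimum
    mismatch count (and that count is within ``max_mismatch_frac``).
    Reads with zero or multiple equally good placements are discarded and
    counted. Forward orientation only: reads are sense-strand cDNA mapped
    back to transcript contigs.
    """
    stats = stats if stats is not None else MapStats()
    index: dict[str, list[tuple[int, int]]] = {}
    seqs = [c.sequence for c in contigs]
    for ci, seq in enumerate(seqs):
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((ci, i))

    out: list[AlignmentRecord] = []
    for read in reads:
        rseq = read.sequence
        n = len(rseq)
        if n < k:
            stats.unmapped += 1
            continue
        offsets = list(range(0, n - k + 1, k))
        if offsets[-1] != n - k:
            offsets.append(n - k)
        candidates: set[tuple[int, int]] = set()
        for off in offsets:
            for ci, pos in index.get(rseq[off:off + k], ()):
                p0 = pos - off
                if 0 <= p0 <= len(seqs[ci]) - n:
                    candidates.add((ci, p0))
        if not candidates:
            stats.unmapped += 1
            continue
        best: tuple[int, int] | None = None
        best_mm = n + 1
        tie = False
        for ci, p0 in sorted(candidates):
            mm = _hamming(rseq, seqs[ci][p0:p0 + n])
            if mm < best_mm:
                best, best_mm, tie = (ci, p0), mm, False
            elif mm == best_mm:
                tie = True
        if tie:
            stats.ambiguous += 1
            continue
        if best_mm > max_mismatch_frac * n:
            stats.unmapped += 1
            continue
        ci, p0 = best  # type: ignore[misc]
        out.append(AlignmentRecord(
            read_id=read.id, genotype_tag=genotype_tag,
            contig_id=contigs[ci].id, pos=p0 + 1,
            cigar=f"{n}M", sequence=rseq))
        stats.placed += 1
    return out


# ---------------------------------------------------------------------------
# truth-table serialization
# ---------------------------------------------------------------------------

def variants_frame(truth: TruthSet) -> pd.DataFrame:
    rows = []
    for v in truth.variants:
        row = {"contig": v.contig_id, "pos": v.pos, "is_het": v.is_het,
               "kind": v.kind}
        row.update({f"allele_{g}": a for g, a in v.alleles.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def ssrs_frame(truth: TruthSet) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig": s.contig_id, "start": s.start, "end": s.end,
          "motif": s.motif, "count": s.count} for s in truth.ssrs])


def read_variants_frame(df: pd.DataFrame, genotypes: Sequence[str]) -> list[PlantedVariant]:
    out = []
    for _, r in df.iterrows():
        alleles = {g: str(r[f"allele_{g}"]) for g in genotypes}
        out.append(PlantedVariant(str(r["contig"]), int(r["pos"]), alleles,
                                  bool(r["is_het"]), str(r["kind"])))
    return out


def write_truth(truth: TruthSet, out_dir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, junction TSV and truth tables; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "junctions": out / "junctions.tsv",
        "variants": out / "variants.tsv",
        "ssrs": out / "ssrs.tsv",
    }
    write_fasta(truth.contigs, paths["reference"])
    write_junction_tsv(truth.junctions, paths["junctions"])
    variants_frame(truth).to_csv(paths["variants"], sep="\t", index=False)
    ssrs_frame(truth).to_csv(paths["ssrs"], sep="\t", index=False)
    return paths


def write_reads(reads: Mapping[str, list[QualityRead]], out_dir: str | Path,
                ) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for g, lst in reads.items():
        p = out / f"reads_{g}.fastq"
        write_fastq(lst, p)
        paths[g] = p
    return paths
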