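# capsimark

SNP and SSR marker discovery from transcriptome assemblies of inbred
pepper (*Capsicum annuum*) lines — a tested, reusable re-implementation of
a classic marker-mining computation, with a synthetic-data generator that
replaces the original multi-hundred-million-read sequencing deposits so
every stage can be exercised and verified offline.

## Who this is for

Researchers building genetic markers from transcriptome (EST or short-read)
assemblies of inbred crop lines, and anyone who needs a transparent,
deterministic reference for the filtering rules these pipelines apply.

## What it computes

**Three-genotype pileup SNP calling (the "2-of-3" rule).** Reads from three
homozygous lines are mapped to consensus contigs and piled up per line. At
each position a line is genotyped from its base counts (depth *d*, major
base fraction *f*):

* `hom(b)` if *d* ≥ 10 and *f* ≥ 0.9,
* `het` if *d* ≥ 10, *f* < 0.9 and the second allele has ≥ 2 reads,
* `low_depth` otherwise.

A position is a putative SNP iff all three lines are homozygous, two share
one allele and the third carries a different one. Positions with any
heterozygous line call go to a separate track. Putative SNPs are then
filtered: a kept SNP must lie ≥ 50 bp from every exon–exon junction, every
other candidate SNP and every heterozygous position, and must have ≥ 20
reads summed across lines (distance "at least 50 bp" is read as ≥ 50, so a
distance of 49 fails).

**EST-contig SNP calling.** Members of a multi-EST contig are piled on the
consensus; a position is a putative SNP when ≥ 2 distinct bases each reach
depth 2. SNPs within 50 bp of a contig end are dropped; of two SNPs closer
than 50 bp, only the higher-coverage one survives (tie → leftmost).

**SSR discovery.** Maximal perfect tandem repeats of 2–6-nt motifs at
thresholds (unit/min repeats) 2/6, 3/5, 4/5, 5/5, 6/5; SSRs separated by
≤ 100 bp merge into compound SSRs; motifs are grouped into
strand/phase-independent classes (AG/CT, AAC/GTT, AT/TA, …); each SSR can
be emitted as a Primer3 boulder-IO task (product 100–300 bp, optimal
Tm 60 °C, optimal primer length 20 nt).

**Cross-assembly marker comparison.** Each filtered SNP becomes a 101-nt
window with the SNP at the center. Two SNP sets are compared by optimal
local alignment of windows (match +1, mismatch −2, gap open −5/extend −2,
both orientations); a valid hit needs ≥ 80 matching bases, and a SNP is
*common* only when best valid hits are reciprocal. A 95 %-identity variant
of the same lookup locates assay windows in another assembly.

**Summary statistics.** N50 (length-weighted median), GC% (N excluded),
contig size bins, and marker densities (e.g. one SNP per 2,798 bases),
all rounded half-up at the reported precision.

## Worked example

```python
import capsimark as cm
from capsimark import snp_discovery as snp

cfg = cm.SimConfig(n_genes=12, seed=14, error_rate=0.0)   # three lines, depth 20
truth = cm.simulate_truth(cfg)
reads = cm.simulate_reads(truth, cfg)
alignments = []
for line, lst in reads.items():
    alignments.extend(cm.naive_map(lst, truth.contigs, line))

pile = snp.build_pileup(alignments, truth.contigs, genotypes=list(cfg.genotype_names))
rows = snp.genotype_rows(pile, truth.contigs)
candidates, het_track = snp.call_iga_snps(rows)
kept, flagged = snp.filter_iga_snps(candidates, het_track, truth.junctions)
```

Summarizing those objects (counts, one kept SNP, assembly statistics and
marker density) prints:

```
planted: 15 SNPs (11 clean), 2 het sites, 2 SSRs
called:  15 candidates -> 11 kept, 4 flagged, 2 het positions
example: contig0002:411 T->G {'CM334': 'G', 'Maor': 'T', 'EJ': 'T'} depth=61
assembly: 12 contigs, 25105 nt, N50=2220, GC=49.9%
density: 1 SNP per 2282 bases
```

Every planted SNP was re-identified as a candidate; the 11 that respect all
50-bp distance rules are kept, and the 4 deliberate violators (near a
junction, adjacent pairs, next to a heterozygous site) are flagged with the
specific rule they break. The example SNP shows CM334 homozygous G where
Maor and Early Jalapeño are homozygous T at depth 61 across lines.

The same stages run from the shell:

```bash
capsimark run --seed 42 --out-dir run1        # simulate → … → stats + manifest
capsimark trim --policy stringent --in r.fastq --out r.trim.fastq
capsimark iga-snp --sam a.sam --ref contigs.fa --junctions j.tsv \
          --out snps.vcf --table snps.tsv
capsimark ssr --fasta contigs.fa --out ssr.tsv --p3 primer3_input.txt
```

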