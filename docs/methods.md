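# Methods

## The marker-discovery model

The package operates on transcript contigs (a consensus assembly) and
treats two sources of polymorphism evidence:

1. **Pileup genotyping across inbred lines.** Three near-isogenic,
   essentially homozygous genotypes are sequenced separately and mapped to
   one consensus. Because the lines are inbred, a true polymorphism shows
   as *different homozygous* calls between lines; a within-line mixed
   signal (heterozygous call) indicates residual heterozygosity, a
   collapsed paralog or a mapping artifact, and disqualifies not only the
   position but — through the 50-bp adjacency rule — its neighborhood.
   The 2-of-3 rule (two lines share a homozygous allele, the third line is
   homozygous for another) yields biallelic, assay-friendly candidates.

2. **EST-contig mining.** Older capillary-sequenced EST assemblies carry
   polymorphism between the individuals whose cDNAs were pooled. With
   much lower depth, the caller only requires two distinct alleles with
   ≥ 2 supporting sequences each; contigs built from a single sequence
   cannot be examined at all.

The distance filters encode assay design reality: markers are genotyped by
PCR on *genomic* DNA, so a SNP within 50 bp of an exon–exon junction may
have an intron under its primer; clustered SNPs and nearby heterozygous
positions similarly compromise allele-specific primers. Filtering is
deliberately conservative — flags are attached, not silently dropped, and
the candidate set always partitions exactly into kept + flagged.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_line_depth` | 10 reads | per-line floor for any genotype call |
| `hom_fraction` | 0.90 | major-base fraction for a homozygous call |
| `het_min_count` | 2 reads | minor-allele support for a heterozygous call |
| `filter_window` | 50 bp | exclusion radius around junctions / SNPs / hets |
| `total_min_depth` | 20 reads | depth floor for a kept SNP (summed over lines; `depth_mode="per_line"` applies it per line instead) |
| `est min_allele_depth` | 2 | per-allele depth in the EST caller |
| SSR thresholds | 2/6, 3/5, 4/5, 5/5, 6/5 | unit size / minimum repeats |
| `max_spacer` | 100 bp | maximum gap inside a compound SSR |
| window | 101 nt | SNP-centered fragment for cross-assembly comparison |
| `min_matches` | 80 | matching bases for a valid window hit |
| `min_identity` | 0.95 | identity cut for the assay-window lookup |
| trim (normal) | Q20, 40–85 nt | end-strip threshold and length gate |
| trim (stringent) | 10 nt 5', 5 nt 3', 25–70 nt | fixed cuts after normal trimming |

The homozygous fraction and the heterozygous minor-allele count are not
fully determined by the depth-10 rule alone; 0.9 and 2 are the package
defaults, exposed as configuration keys, and the planted-truth recovery
properties hold for any `hom_fraction` in (0.5, 1]. The depth floor of a
kept SNP is applied to the summed depth by default, with a per-line mode
available, since either reading is defensible.

Every distance is `|pos_a − pos_b|` in contig bases and "at least 50 bp"
means ≥ 50 (49 fails). The contig-end rule in the EST path excludes
positions 1–50 and the last 50 positions.

## Local alignment engine

Window comparison uses Biopython's `PairwiseAligner` in local mode with
match +1, mismatch −2 and affine gaps costing 5 + 2·k for a length-k gap.
Scores are scaled so that among score-co-optimal alignments the one with
the most matching columns is chosen (a full-length alignment beats one
with score-neutral trimmed ends); this makes the ≥ 80-match rule
deterministic. Reverse-complement orientation is always tried; forward
wins ties. Fixed match-count and identity cuts replace heuristic-search
E-values: with the window length pinned at 101 nt they are the operative
criterion, and they make results independent of database size and
bit-reproducible. A hand-written Gotoh dynamic program serves as the
independent oracle in the test suite, never as the implementation.

## SSR scanning

The scanner reports, per unit size 2–6, every leftmost-maximal perfect
tandem run meeting its repeat threshold, truncated to complete units; `N`
breaks runs; a run whose motif is itself a tandem of a smaller unit (ATAT
as a 4-mer) is reported only at the smaller unit. Where a maximal run can
be framed several ways (…GGAAGAAGAAG…), the leftmost frame is reported,
so the motif may be a rotation (GAA) of the "alphabetical" class member.
Overlapping runs of different, non-reducible unit sizes are each reported
and may merge into a compound record. Mononucleotide runs are not treated
as markers (the threshold table starts at dinucleotides). Canonical class
labels take the lexicographically smallest rotation of motif or reverse
complement as representative, and print it with the smallest *other*
rotation of the representative's reverse complement — yielding the
field-standard labels AG/CT, AAC/GTT and, for palindromic classes, AT/TA.

## The synthetic experiment

`synthetic_data` emulates the structure — not the biology — of a
three-line inbred transcriptome study:

* multi-exon transcript contigs (1.5–2.5 kb, exons ≥ 60 nt) with junction
  coordinates at the cumulative exon boundaries;
* planted biallelic SNPs at ~0.4/kb (about one per 2.5 kb, matching the
  observed transcriptome density), each homozygous in all lines with one
  line carrying the alternate allele; a configurable fraction (default
  25 %) deliberately violates one filter each (within 49 bp of a junction,
  adjacent pairs, or adjacent to a planted heterozygous site);
* residual heterozygous sites at ~0.1/kb in one line;
* planted SSRs with maximality guards so their exact span is recoverable;
* single-end 85-nt sense-strand reads at mean depth 20 per line with
  uniform substitution errors and a linear positional Phred decay.

Two deliberate variance-reduction choices make the recovery properties
test the *caller* rather than coverage luck: read starts are
stratified-uniform (one start per equal-width interval, so interior depth
concentrates tightly around the mean), and at heterozygous sites the two
alleles alternate read-by-read (an exact 50/50 draw). Marginally, starts
are uniform and het alleles are 50/50. Features are planted on anchors
≥ 150 nt from contig ends and ≥ 110 nt from junctions, so clean sites sit
in flat-coverage territory and violators never contaminate a clean site's
50-bp neighborhood.

The built-in mapper indexes contigs by 21-mers and places each read
end-to-end, ungapped, at its unique Hamming-best position; reads with no
seeded candidate or with tied best placements are discarded and counted.
Reads are mapped forward-only (sense-strand cDNA against transcript
contigs). Paired-end geometry, expression-level variation, indels and
realistic error profiles are intentionally absent: they exercise the
aligner, not the callers under test. Consequently, passing recovery tests
demonstrates the correctness of the calling and filtering logic under
clean mappings — not robustness to real-world mapping noise, structural
variation or paralogy.

## Numerical and degenerate-input choices

* All reported figures round half-up at their printed precision through
  one shared helper (`round_half_up`); N50 is the standard sort-descending
  accumulation; GC% excludes N from the denominator; density with zero
  markers is reported as NA rather than raising.
* Count ties in the EST caller resolve lexicographically; tri-allelic
  columns are emitted with a flag (downstream defaults exclude them)
  rather than dropped silently.
* The EST adjacency filter is a greedy left-to-right pass re-evaluating
  against the surviving SNP; coverage ties keep the leftmost.
* Quality trimming strips single terminal bases while below Q20 (a plain
  end-strip loop, not a running-sum algorithm); trimming is idempotent.
* Internal coordinates are 0-based half-open; every serialized coordinate
  (VCF, TSV, SSR table, Primer3 target) is 1-based inclusive. Only
  Phred+33 FASTQ is accepted. IUPAC ambiguity codes map to N with a
  logged count, since the callers treat non-ACGT as no-information.
* Reciprocal comparison uses best-hit pairing (max matches, ties to the
  first subject); with the symmetric scoring this makes
  `common(A,B) = common(B,A)` exact, and common + unique always
  partitions each input set.

## Known limitations

* The naive mapper is a testing device for synthetic data, not a
  production aligner; real read sets should be mapped externally and
  supplied as SAM.
* Indels are not called; the pileup treats D ops as missing information.
* SSR detection is perfect-repeat only (no mismatch-tolerant runs), and
  primer design itself is delegated to an external Primer3 run — the
  package only generates tasks and parses results.
* Cross-assembly SSR matching defines its own reproducible criterion
  (identical class and count plus an 80-base flank match, greedy best
  hit); published "unique SSR" totals derived from other criteria are not
  reproduced.
* Adapter contamination is assumed removed upstream (a hook exists for an
  external trimmer).
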