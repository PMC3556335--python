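# Methods

This note records the models, rules and numerical choices behind
`detriage`, in the order the pipeline applies them, together with what the
synthetic study does and does not emulate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GFF3 and VCF are converted
at the I/O boundary and writers restore the native convention, so
read∘write round-trips are the identity. Spliced alignments travel as
BED12 with two extension columns (13: alignment identity, 14: query
coverage, fractions in [0,1]) because standard BED12 has no slot for them;
a chimeric contig occupies several BED12 lines sharing a name, numbered as
segment groups in file order. VCF alternative-allele frequency prefers
INFO/AF and falls back to AO/(AO+RO); rows with neither are excluded with a
warning and counted, never dropped silently. Parsers report read/kept/
rejected counts that must sum.

## Read-pair geometry and coverage classes

The mate spacer of a paired-end library is `fragment_mean − 2·read_length`
with the fragment SD unchanged (reads have fixed length); overlapping mates
(fragment < 2 reads) are rejected rather than modelled. Genome coverage is
the per-base count of alignment blocks; covered bases (default threshold
3×, configurable because the classification should be robust to 6× or 10×)
are partitioned exon > intron > intergenic: a base exonic in any isoform
counts as exonic, intronic means inside a transcript span but in no exon of
that chromosome. The partition is exact — class counts always sum to the
covered total.

## Variant filtering and effect projection

Variants pass when depth ≥ 5, call quality ≥ 80 and alternative-allele
frequency ≥ 0.75, all inclusive. Region classification uses a ±2 bp
splice-site window inside the intron (the canonical donor/acceptor
dinucleotides; the window is a package choice, as only the category itself
is standard). When a variant hits several transcripts the most severe
region is reported, ordered splice_site > CDS > UTR > intron.

Coding consequences are derived by translation, not by table lookup: the
spliced CDS (exons ∩ CDS span, reverse-complemented on the minus strand) is
mutated and both proteins compared. A new in-frame stop before the terminal
codon is `stop_gain`; loss of the terminal stop is `stop_loss`; otherwise
any residue change is `missense`, none is `synonymous`. Indels are
`frameshift` when the length difference is not a multiple of 3, else
`in_frame_indel`. Multi-base substitutions are decomposed base-by-base and
the most severe consequence kept. A reference CDS whose length is not a
multiple of 3 is an annotation fault and an error. Gene-level roll-up:
*potentially destroyed* iff any transcript carries frameshift, stop gain,
stop loss or a splice-site hit; *changed* iff (not destroyed and) any
missense or in-frame indel.

## Contig triage

**Clustering.** Redundant contigs are collapsed greedily: visit contigs
longest-first (ties by id); join the first cluster whose representative
aligns with identity strictly above 0.90 over 100% of the shorter sequence
(infix alignment via edlib, so coverage-of-shorter is 1 by construction);
otherwise found a new cluster. The canonical sort makes the result
input-order invariant. A k-mer containment mode (exact 31-mers) exists for
settings where full alignment is unnecessary.

**Gating.** A contig is chimeric when ≥ 2 alignment segments, each covering
≥ 20% of the query, lie on different chromosomes, different strands, or
more than 1 Mb apart — an explicit, reproducible stand-in for what spliced
aligners flag internally. Otherwise the best single segment (highest query
coverage, then identity) must reach 90% identity and 90% query coverage.

**Structure filter.** Multi-block alignments are kept. Single blocks are
removed when they match one annotated exon within ±10 bp per end
(`single_exon`; the slack absorbs assembly end errors), lie strictly inside
one exon (`exon_fragment`), or overlap an annotated intron by more than
half the block (`partial_intron`). Surviving single blocks in annotated
regions stay in play (they are the intron-retention candidates the FMI
filter judges); in empty regions they are retained as potential novel
single-exon loci only at ≥ 200 bp.

**Loci.** A contig joins the annotated gene with which it shares exonic
overlap on a compatible strand (unstranded alignments match either strand);
exonic overlap with ≥ 2 genes creates a merged locus naming the members —
evidence that the annotation split one gene. Contigs overlapping no gene
but an annotated repeat are repeat-region; the rest are grouped into novel
loci by single-linkage interval overlap.

**FMI filter.** Within each locus the major isoform is the highest-FPKM
member (ties by id) and is always kept; any other member is discarded as
pre-mRNA when its FPKM is *strictly below* 5% of the major's ("fell below"
read literally — exactly 5% survives). The threshold is configurable (10%
and 15% are natural sensitivity settings). An all-zero locus is kept whole
with a warning. Per-contig FPKM is an input; how it is computed from reads
is outside this package.

**Isoform comparison.** A surviving contig is *identical* iff its ordered
intron-interval chain (target gaps between blocks) equals that of some
reference transcript at the locus, else a *novel isoform*; a single-block
contig at a multi-exon locus is therefore novel. The comparison is exact by
design; tolerance for jittered boundaries belongs to the aligner, not to
the chain comparison.

## Novel loci and unmapped contigs

Homology evidence is first gated at E ≤ 1e-5 and query coverage ≥ 20%.

**Coding potential** is a transparent heuristic taking the decision role of
a trained coding/non-coding classifier: the score is
0.7·(longest-ORF fraction of the contig) + 0.3·(codon-position bias), where
the bias is the mean total-variation distance between the nucleotide
compositions of the three codon positions of the longest ORF (≈ 0 for
random sequence, elevated for real coding sequence, requiring ≥ 30
usable bases). A contig is coding when it has an ORF of ≥ 33 codons
(~100 nt, the common convention) and score ≥ 0.5. The ORF scanner reports
one maximal ORF per inter-stop segment in each of six frames; completeness
is *full* only with both ATG and in-frame stop inside the contig, and ORF
lengths count the stop codon.

**Novel-locus tree**, in precedence order: transposon-protein similarity
(before the coding check — a coding transposon is still a transposon);
coding potential (full vs partial ORF); nr/plant protein homology; RNA
family similarity; default putative ncRNA. The call depends only on the hit
set and the sequence, never on hit order.

**Unmapped tree**: (1) best nr-protein hit (bitscore, then e-value) with a
taxon outside Viridiplantae → contaminant; ties among equal-score best hits
with conflicting taxa resolve conservatively to contaminant; (2) a
raw-genome-read hit → missing-from-assembly (a gap in the reference, not a
private gene), with a coding subclass; (3) an expressed-plant-sequence or
plant-protein hit → private candidate; (4) otherwise no evidence. Private
candidates are clustered single-linkage: an edge joins two candidates
sharing a best database subject or aligning to each other with identity
> 0.90 over ≥ 80% of the shorter sequence; the longest member represents
the cluster and carries its coding flag.

## Expression profiling

FPKM = count / (exon-model kb × millions of mapped fragments). The 95% CI
is a count-level normal approximation, count ± 1.96·√count floored at 0,
with an upper bound of 3.84 (= 1.96²) for a zero count, rescaled to FPKM
units; a principled exact interval would change little at the counts that
matter. A gene is expressed iff CI low > 0 and FPKM > 0.001, both strict.

Size factors are median-of-ratios over features nonzero in every sample;
when no such feature exists a pseudo-reference fallback (geometric mean
over positive counts) is available behind an explicit flag.

The differential test is an exact-style conditional NB test between two
stages: replicate sums per stage are modelled as negative binomials sharing
the pooled mean q (mean per unit size factor), with variance
μ + α·q²·Σsⱼ²; conditional on the observed total, the two-sided p-value
sums the probabilities of all splits at most as likely as the observed one.
The dispersion α is a per-feature method-of-moments estimate on normalized
counts, taken as the **maximum over the two conditions** and multiplied by
an **n/(n−1) small-sample correction** (n = smaller replicate number):
MoM dispersion from three replicates is biased low, and with no
cross-feature sharing the explicit correction plays the role that
conservative dispersion treatment plays in count-based DE packages.
The floor is 1e-8. Simulations in the test suite put the type-I error
around 3–5% at nominal 5% (dispersion 0.1, n = 3 vs 3) with full power for
8-fold changes at mean 200. Numerical parity with any specific DE package
is *not* claimed; calibration by simulation is the contract. All-zero
features get p = 1 and are excluded from the BH denominator; log2 fold
changes use normalized means with pseudocount 1.

The moderated fold change is a shifted log: difference of mean
log2(normalized count + c) with c = 8, chosen so that low-count fold
changes are damped (|moderated| ≤ |raw|) while the estimate converges to
the raw log-ratio for large counts (difference < 0.01 by mean 10⁴). It
stands in for a variance-stabilizing transformation whose only role here is
fold-change moderation before profile assignment.

Profiles use the two adjacent-stage contrasts (PFS→PR, PR→PHWII). With
signed significance d ∈ {−1, 0, +1} per contrast (significant iff
FDR ≤ 0.05 and |log2FC| ≥ 1): (−,−), (−,0), (0,−) → cluster 1 repressed;
(−,+) → 2 transiently repressed; (+,−) → 3 transiently induced; (+,+),
(+,0), (0,+) → 4 induced; (0,0) → none. (The FDR default follows the
methods-level 5% figure; the stricter 0.05% variant is a configuration
away.) Enrichment is the hypergeometric upper tail per (group, term) with
BH across terms within each group; terms with no universe members are
skipped.

## The synthetic study

The generator emulates the *structure* of a cultivar-vs-reference
transcriptome study at desk scale: two 500-kb chromosomes, 60 genes (2–5
exons of 150–450 bp, introns 100–300 bp, UTRs 20–60 bp, valid ATG…stop CDS
on both strands, some genes with a second exon-skipped noncoding isoform),
four adjacent same-strand gene pairs reserved for read-through contigs,
hidden novel coding/noncoding loci written into the sequence but not the
annotation, and annotated repeats. Planted contigs cover every triage
class; planted variants cover every effect class (30 each by default, 240
total) plus decoys failing exactly one filter (depth 4, quality 79, or
frequency 0.74); counts are NB (mean 200, dispersion 0.05) for 3 stages ×
3 replicates with 8-fold planted patterns, 30 features per pattern among
200. Truth tables cover every entity exactly once and a fixed seed
reproduces every output byte-for-byte.

Alignments are emitted from generative truth rather than computed by an
aligner — the triage logic, not alignment, is under test. Default noise is
a 1% substitution rate on contig sequences (reflected in the emitted
identity values); an opt-in error mode additionally jitters block edges by
±5 bp to exercise the structure-filter tolerances, and is off by default
because it deliberately breaks exact intron-chain equality. What passing
tests therefore show is that the *decision rules* are implemented exactly
and are robust to sequence-level noise; they do not show robustness to
aligner idiosyncrasies (soft-clipping, boundary wobble, multi-mapping) or
to expression-estimation error, which real data would add.

## Problem sizes and determinism

Default sizes (60 genes, ~65 contigs, 252 variants, 200 features; 1000-
feature null calibration and 10×100-feature power tables) keep the full
suite and the acceptance script in the tens of seconds on one core while
leaving every class populated. All randomness flows from
`numpy.random.default_rng` seeded per component, so identical configuration
and seed give identical files (hash-checked in the tests).

## Known limitations

- Coding potential is a heuristic, not a trained classifier; its role is
  the binary decision in the trees, and borderline sequences (short ORFs,
  unusual composition) will be called conservatively noncoding.
- The contaminant rule reduces taxonomy to the label carried by the hit
  table; there is no lineage resolution beyond plant vs non-plant.
- The NB test estimates dispersion per feature with no information sharing;
  at very low counts it is conservative.
- Evidence overlap and locus assignment count ≥ 1 bp exonic intersection;
  no attempt is made to weight by overlap length.
- The FMI filter judges pre-mRNA purely by relative expression; an
  intron-retaining isoform expressed above the threshold is (correctly, by
  the rule) reported as a novel isoform.
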