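# Methods

`bsamap` implements an interspecies bulk-segregant analysis (BSA): mapping a
monogenic, recessive-style trait that segregates in a cross between two
yeast-like species whose genomes are fully collinear but ~10% diverged at
the nucleotide level. Because nearly every 51-bp window differs between the
parents, reads from pooled progeny can be assigned to a parent by exact
matching alone, without variant calling. This note records the model, the
defaults and why, the numerical choices, and what the synthetic data do and
do not establish.

## The experimental design being modelled

Two haploid parents — A, carrying the functional allele of the trait gene,
and B, carrying a defective allele — are crossed; the hybrid diploid is
sporulated; haploid segregants are phenotyped (here: able vs. unable to
switch mating type) and typed for mating type; and four pools are sequenced
(phenotype x mating type), together with both parental strains. A locus
causing the phenotype shows biased parental inheritance in opposite
directions in the two phenotype pools; everywhere else inheritance is ~50:50.

## Read assignment

A read is retained only if it has **exactly one** perfect, full-length match
in one genome (counting both strands) and **no** perfect match in the other.
Five mutually exclusive categories are produced: `exclusive_A`,
`exclusive_B`, `shared` (perfect in both), `multimapped` (two or more
matches within the only matching genome), `unmatched`. Choices worth
stating:

* "Single perfect match" is read strictly: multi-mapping within the
  favoured genome disqualifies the read.
* Reads containing N are unmatched by construction.
* A read identical to its own reverse complement that hits one site counts
  two occurrences (one per strand) and is therefore multimapped. This is
  literal occurrence counting, stated for reproducibility; at 51 bp it is
  vanishingly rare.

The index is an exact-substring hash over every window of the read length;
its results are testably identical to a position-by-position scan.

## Segmentation

The two genomes are partitioned into alternating segments: one **gene**
segment per collinear ortholog pair and one **intergenic** segment between
consecutive pairs. A chromosome with *g* ortholog pairs yields 2*g*+1
segments because the two chromosome-end flanks are also emitted (as
intergenic, flagged `terminal`): this guarantees every read start has a
segment, so counting conserves reads. With the default 7 x 10 gene layout
the genome has 147 segments. Reads that span a segment boundary are
credited to the segment containing their start coordinate — a single
deterministic rule whose effect is negligible at 51 bp against multi-kb
segments. Intergenic segments may contain species-specific genes; no
special handling. All intervals are half-open, 0-based internally, with
1-based GFF3 on emission.

## Ratios and the asymmetry statistic

Each pool is mapped against each reference separately, so each
(library, genome) combination has its own total of retained reads, N[lib, g].
Per segment *s*:

    SW_A(s) = ( n[s, SW, A] / N[SW, A] ) / ( n[s, parent_A, A] / N[parent_A, A] )

and analogously NS_A, SW_B, NS_B. With this normalization a segment with
unbiased inheritance has expected ratio 1 in every pool; a segment at which
every clone of a pool inherited one parent approaches 2, because a pool of
50:50 mosaics retains roughly half of either parent's total. The statistic

    asymmetry(s) = max(SW_A - 1, 0) * max(1 - NS_A, 0)
                 * max(NS_B - 1, 0) * max(1 - SW_B, 0)

is zero unless all four inheritance biases point in the phenotype-predicted
direction simultaneously, which makes it extremely quiet under the null.
Design choices:

* **Zero-denominator segments score 0**, not a pseudocount-inflated value:
  the metric is "zero unless evidence". A pseudocount option (add alpha to
  every count) exists, default off.
* **No smoothing across segments** — the statistic is plotted and ranked
  raw, preserving single-gene resolution.
* **Peak calling**: maximal runs of segments with asymmetry above a
  threshold (default 0, i.e. any positive run), ranked by apex value, ties
  broken by genomic order. Apex values are reported so users can impose
  their own thresholds; no significance is attached.
* The statistic is symmetric under jointly swapping genome labels and pool
  roles, so the parent labelled "A" is a convention, not an assumption.

## Loss-of-function screen

Every ortholog pair inside a candidate peak is aligned globally
(match +1, mismatch -1, gap open -4, gap extend -1; a gap of length L costs
4 + (L-1)). Gap runs are reported as indel events with their frame effect
(length mod 3) and a running cumulative frame, so compensating indels are
recognized as frame-restoring. Translation runs from position 1 to the
first in-frame stop; a non-ATG start or trailing bases are flagged, not
fatal. Pairs are ranked frameshift > premature stop > in-frame indel >
substitutions only.

Gap placement inside a mononucleotide run is degenerate (the classic
"extra T in a T-run" situation), so every gap run is normalized to its
leftmost equivalent position; reported coordinates are therefore
deterministic. When a substitution abuts the indel, equally optimal
alignments can still place the gap a base or two away from the mutational
event, so a reported indel coordinate may differ from the planted offset
by that much — an intrinsic ambiguity of alignment-derived coordinates,
not an error. Scoring parameters are fixed and recorded rather than
tunable, preferring reproducibility. A premature stop is called relative
to the full-length product implied by each sequence's own reading frame.

## The synthetic cross

The generator's defaults are the study conditions:

| parameter | default | why |
|---|---|---|
| chromosomes | 7 | both species have 7 collinear chromosomes |
| orthologs per chromosome | 10 | enough segments (147) for peak structure at desk scale |
| gene length | 900–1500 nt | typical yeast CDS lengths |
| intergenic length | 300–800 nt | typical compact yeast spacing |
| divergence | 0.10 subst./site | the two parents are ~10% diverged |
| intergenic micro-indels | 0.01 /site | indel divergence without disturbing ORFs |
| causal CDS length | 1314 nt | intact allele encodes a 437-residue protein |
| causal insertion offset | 512 | 1-based CDS position of the planted extra base |
| segregants screened | 400 | see below |
| pools | 30/35/35/52 | the four phenotype x mating-type pool sizes |
| crossovers/chromosome | 2.0 (Poisson, uniform, no interference) | simplest model; gives multi-segment linkage decay |
| penetrance / misclassification | 1.0 / 0.0 | clean phenotyping of clear phenotypes |
| read length | 51 nt, unpaired | matches the sequencing design |
| per-clone coverage | 0.5x | pool coverages of 15–26x |
| parent coverage | 20x | stable per-segment denominators |
| sequencing error | 0.002 /base | short-read substitution error scale |

**Why 400 segregants when the pools sum to 152.** Pooling requires 52
non-switcher MATa clones, but each phenotype x mating-type class captures
only ~25% of screened clones, so 152 screened clones cannot reliably fill a
52-clone pool; the experiment this emulates likewise pooled only clones
with clear phenotypes from a larger screened set. 400 screened clones make
every class sufficient with high probability while exactly 152 enter pools.

Construction details that keep the ground truth exact:

* Genome A is uniform random DNA with intact ORFs (ATG + non-stop codons +
  stop). Genome B is derived per segment: substitutions everywhere at the
  divergence rate, 1-bp micro-indels confined to intergenic DNA. In genic
  DNA, substitutions that would create an in-frame stop are redrawn, and
  start/stop codons are left untouched, so every non-causal ORF stays
  intact — the design assumes a single causal loss-of-function locus.
* The causal mutation is planted by inserting one base into genome B's copy
  of the target gene so that the new base occupies the configured 1-based
  CDS position. The base is chosen to differ from both CDS neighbours
  (preferring T), making the alignment gap placement unique.
* The true A↔B alignment is carried as per-chromosome match blocks and is
  used only by tests and by mosaic-sequence construction, never by the
  classifier.
* Mating type is a neutral marker gene on chromosome 3: it exists (pools
  are stratified by it and later merged) but is independent of phenotype.
* Optional incompatibility mode: a designated (A-allele, B-allele) gene
  combination is lethal and removed by rejection sampling, which reproduces
  qualitatively a secondary inheritance-bias peak at a locus with no
  disabling mutation.
* Pool reads are drawn per clone with equal weights (each clone's mosaic
  sequence sampled uniformly, both strands equiprobable); an optional
  gamma-dispersion knob for unequal pooling exists but is unvalidated.
  Read counts are deterministic given coverage (rounded expectation), with
  chromosome allocation multinomial.

Everything is a pure function of (config, seed).

## What the synthetic data do not emulate

Base-quality profiles, paired ends, PCR duplicates, coverage biases (GC,
mappability), structural variation between the parents, real ortholog-call
uncertainty, and aneuploid or diploid contaminant clones. Passing tests
therefore demonstrate the correctness of the pipeline's logic under its
stated model, not robustness to every artifact of real libraries. In
particular the real experiment's segment count (thousands of segments from
real annotations) is not reproduced — the segment count here follows the
2g+1 formula of the simulated layout.

## Numerical and degenerate-input choices

* Zero-length intergenic segments (abutting genes) are retained and simply
  collect zero counts.
* Ratio validity is tracked per segment; an invalid ratio (parent count 0)
  zeroes the asymmetry there.
* Crossover counts are Poisson; positions are uniform integers; duplicate
  positions collapse (a double crossover at one point is invisible, as in
  reality).
* The end-to-end run is deterministic: stage RNG streams are derived from
  (seed, stage-tag) so adding a stage never perturbs another stage's draws.
* Problem sizes used by the shipped checks: the recovery and null-
  calibration studies use 20 runs each at the default 7x10-gene scale
  (~130 kb genomes, ~300k reads per run); classifier/oracle agreement uses
  100 random 2-kb genome pairs x 200 reads; alignment optimality uses 1000
  random pairs of length <= 10 nt against exhaustive enumeration.

## Known limitations

* The exact-match classifier is deliberately mismatch-intolerant; with
  higher sequencing error or lower divergence the retained fraction drops.
  This mirrors the design it replaces rather than improving on it.
* Peak significance is not assessed; the ranking is descriptive.
  Resampling-based confidence intervals are a documented extension, not
  implemented.
* The premature-stop call in the screen is frame-based and does not model
  splice forms or translational readthrough.
* Real-data mode (FASTA/GFF3/FASTQ inputs) shares all analysis code paths
  but has no ground truth, so its outputs are rankings, not verdicts.
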