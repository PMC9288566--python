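# Methods

## The measurement problem

An M1 plant regenerated from an MNU-treated fertilized egg cell carries its
induced mutations in the heterozygous state, scattered essentially uniformly
across the genome. Joint genotyping of the whole cohort against one reference
turns mutation discovery into a filtering problem: induced mutations are
*cohort-private heterozygous* calls, while anything shared between plants is a
pre-existing polymorphism against the reference or a systematic artifact, and
anything homozygous cannot be a first-generation induced allele. The package's
curation rule is therefore exact, not heuristic: keep a biallelic record iff
exactly one plant is non-reference for the allele and that genotype call is
heterozygous. Missing genotypes in other plants do not disqualify a site —
at ~15× cohort sequencing depth missingness is routine and carries no evidence
of carriage; the strict alternative (requiring all other plants to be
confidently hom-ref) discards most of the genome and was rejected.

Two further filters follow, in pipeline order unique-het → QV → mask (all
three commute, which the tests verify): site quality strictly greater than a
threshold (default 80, the value at which Sanger validation of this kind of
data plateaus), and removal of InDel calls whose POS falls in a repeat-masked
interval. SNVs in repeats are kept — only InDel calls in repeats are treated
as unreliable. The QV filter uses the joint-genotyping site QUAL; whether a
per-genotype recalibrated score would serve better is not decidable from the
data we model, so the quantity filtered on is a single explicit field and the
threshold a single explicit argument. The mask test uses the variant's
leftmost base rather than its full span — the simplest defensible reading,
and the difference only matters for deletions straddling a mask boundary.

Multi-allelic sites are split into one record per ALT allele at read time;
each split record keeps the site QUAL, and a genotype is reinterpreted
against the split allele (so a 1/2 call is heterozygous for both split
records). Per-plant uniqueness is then evaluated per allele.

## Spectrum, context, rates

Substitutions are tallied in the 12 REF→ALT classes; transitions are the
purine↔purine and pyrimidine↔pyrimidine classes (AG, GA, CT, TC), and Ts/Tv
is their count ratio (reported to 2 decimals, infinite when no transversion
was seen). The G/C→A/T fraction (GA + CT over total) is the alkylation
signature. Window densities are non-overlapping 100-kb tiles by default —
the bar-chart convention — with a `step` parameter for genuinely sliding
windows; the last tile is truncated at the chromosome end and totals are
conserved per chromosome. Mutation rate per Mb is mean per-plant SNV count
divided by an *explicit* genome-size denominator; published per-Mb rates
depend on which assembly span was counted, so no default denominator is
baked in.

The context profile takes every curated SNV with REF = G — plus-strand
orientation only, no reverse-complementing of C>N sites, so the site count
equals the GA+GC+GT class counts of the same curated set and the profile is
directly comparable to a plus-strand random-G null. Each site contributes its
in-range, non-N neighbors to per-offset denominators (sites near chromosome
ends are kept, not dropped). The null is a uniform without-replacement sample
of genomic G positions under a caller-supplied seed. The bias report is the
observed−null difference in percentage points per offset and base, with a
configurable flagging threshold (default 5 pp). A `--collapse-strands`-style
strand-symmetric profile is deliberately not the default.

## Effect annotation

Classification is a fixed decision tree per (SNV, gene) against one
representative transcript per gene — the isoform with the greatest total CDS
length, ties broken by lexicographically smallest transcript id. Inside the
CDS, the reference and alternate codons are built strand-aware (minus-strand
bases complemented into transcript frame) and translated with the standard
genetic code; the categories are start_lost (first codon ATG disrupted),
stop_lost, stop_gained, missense, synonymous, in that precedence. Outside the
CDS: the two canonical intronic bases at each junction are splice_donor
(5' side of the intron in transcription direction) or splice_acceptor, with
donor winning the degenerate tie in introns shorter than 4 bp; exonic
non-CDS positions are UTRs by strand-aware side; other in-gene positions are
intronic; positions within a 5,000-bp window of the gene span (the
conventional default for this kind of annotation, configurable) are
upstream/downstream; everything else is intergenic. One annotation is
emitted per nearby gene; distribution summaries count each variant once at
its most severe annotation (impact rank, then category order). Models whose
CDS length is not a multiple of 3 are annotated best-effort and flagged
rather than rejected; trailing partial codons translate to X.

InDels receive positional annotation only (overlapping gene or intergenic).
Frameshift/in-frame calling is out of scope: the summaries this package
exists to produce are SNV-class tables.

## Saturation extrapolation

"Coverage" is the fraction of annotated genes carrying ≥1 HIGH-impact SNV.
Two extrapolations of cohort size to a target coverage are provided and every
report labels which produced a number: the linear rule n = n_obs·target/obs,
and a Poisson model that treats per-gene hits as independent with per-plant
rate λ = −ln(1−obs)/n_obs, so coverage after n plants is 1−e^(−λn). Linear
cannot represent saturation (and overshoots near 100%); Poisson requires a
target below 1 and always demands at least as many plants as linear above the
observed point. At the observed 8.6% coverage from 266 plants, linear gives
3,093 plants for nominal full coverage.

Seed-setting correlation is plain Pearson r with the two-sided t-transform
p-value on n−2 df (via scipy); a constant series is reported as undefined
rather than zero. No multiple-testing machinery: one test per run.

## The simulator

The generator's defaults are the study conditions; everything downstream is
tested against cohorts drawn from them.

- **Genome**: i.i.d. bases at composition A 0.282, C 0.218, G 0.218, T 0.282
  (the Nipponbare whole-genome composition), 12 chromosomes × 250 kb by
  default. This toy scale keeps a simulated cohort in memory; per-position
  statistics (spectrum, context, annotation categories) are scale-free, while
  absolute totals are not and are never asserted against published totals.
  Toy genes are non-overlapping multi-exon models on both strands with UTRs
  flanking a CDS of whole codons; the first codon is rewritten to ATG and the
  last to a stop so start/stop-affecting categories are exercisable (internal
  stops may still occur in random sequence — the classifier handles them).
  A mask covers ~10% of each chromosome.
- **Per-plant SNV load**: lognormal with log-mean 7.458 and log-sd 0.84,
  matching the observed cohort mean of 2,468.7 SNVs/plant and reproducing the
  observed min–max spread (134–13,222) at n = 266. No distribution family is
  given for the real cohort; lognormal is the standard choice for a positive,
  right-skewed load.
- **Substitution classes**: multinomial on the 12-class probabilities derived
  from the published count table (Ts/Tv 14.81). A drawn class is placed at a
  uniformly chosen genome position carrying that REF base, sampled without
  replacement, so the emitted reference and VCF stay consistent; a genome too
  small for the requested load raises a capacity error.
- **Context bias**: the −1/+1 neighbors of every mutated-G site are resampled
  from the background composition with probability mass added to the favored
  bases (+0.158 A and +0.187 G at −1; +0.064 T at +1) and the remaining bases
  shrunk proportionally; the rewrite lands in the emitted reference FASTA, so
  the analysis recovers the deltas exactly up to sampling. The published
  "increased by 15.8%/18.7%/6.4%" wording is read as percentage-point
  increments over background — the absolute-frequency reading would make A
  *decrease* at −1, contradicting the direction of the reported effect.
  Neighbors that are themselves variant sites are left untouched.
- **InDels**: 0.47% of variants, deletion:insertion 2486:632, sizes 1–10 bp
  with 80.2% shorter than 3 bp (the published size histogram constrains the
  short fraction and direction mix; the within-tail decay is a chosen
  geometric-like shape). True InDels are placed outside the repeat mask: in
  the real pipeline masked InDel calls are discarded as artifacts, so a
  "true" masked InDel would be unrecoverable by construction and would make
  the no-noise recovery limit unattainable for a reason that has nothing to
  do with the filters under test.
- **Call noise**: false positives are 10% of emitted calls (a value chosen
  once to make QV calibration non-trivial while leaving a high post-filter
  true-positive rate, in the spirit of the published ~99% at QV > 80), 2% of
  them InDels — which puts the InDel share of a validation subsample's
  failures near the published one-third. FP QVs ~ Uniform(30, 100), true QVs
  ~ Uniform(60, 500): overlapping enough that thresholding is a real decision.
- **Phenotype**: seed-setting % = clamp(49.5 − 0.006·load + N(0, 21.8²),
  0, 100). The noise SD was calibrated once by Monte Carlo so that the
  *post-clamp* fitted Pearson r at n = 266 averages −0.43 (clamping at 0
  attenuates the correlation, so the pre-clamp target is deliberately
  steeper); the constant is frozen in the default config. The intercept and
  slope put the cohort mean near the observed ~35% seed setting.
- **Transmission and validation**: each true variant transmits with
  probability 1 − 0.152; the validation table subsamples 101 SNVs and 16
  InDels (the published Sanger panel sizes) with `confirmed` equal to ground
  truth.
- **Determinism**: one `numpy` Generator drives everything; a given config
  and seed reproduce all seven output files byte-for-byte.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: read-level error processes (alignment artifacts,
soft-clip false positives, depth-dependent genotype quality), M1 chimerism
and sectoring, linkage between nearby mutations, shared polymorphism against
the reference, and any non-uniform mutation landscape along chromosomes.
Spectrum, context and annotation recovery are structural checks of the
analysis code, not evidence about biology.

## Numerical and reporting choices

Percentages in tables are rounded to 1 decimal (2 for spectrum class
percentages), ratios to 2 decimals, matching the conventions of the tables
they mirror. Thresholding is strictly greater-than. Calibration rows with an
empty numerator report an undefined percentage rather than 0 or 100.
Stochastic tests run at fixture scale (1–3 Mb genomes, 2–20 plants, 10⁴–10⁵
SNVs — sizes at which the asserted 3σ multinomial/binomial bounds are tight
enough to be meaningful) with fixed seeds throughout; the acceptance script
re-derives its statistic from a fresh 100,000-SNV simulation under whatever
seed it is given.
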