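# mnucohort

Analysis toolkit for whole-genome-sequenced mutant libraries produced by
chemical mutagenesis — specifically M1 rice cohorts in which fertilized egg
cells were treated with *N*-methyl-*N*-nitrosourea (MNU) and every plant was
short-read sequenced against its reference genome. The package is aimed at
plant geneticists building "in silico TILLING" resources: instead of PCR
screening thousands of plants per target gene, the whole cohort is sequenced
once and mutation carriers are looked up in an index.

It implements the full desk side of such a study:

- **Curation** of a joint-genotyped multi-sample VCF down to induced
  mutations. MNU mutations in an M1 plant are heterozygous and private to that
  plant, so a call is kept iff exactly one plant is non-reference *and* that
  call is heterozygous; low site-quality calls (QV ≤ 80 by default) and InDel
  calls inside repeat-masked intervals are removed. A calibration routine
  reproduces the Sanger-validation view: true-positive percentage as a
  function of the QV threshold.
- **Spectrum statistics**: the 12-class REF→ALT substitution table with the
  transition/transversion (Ts/Tv) ratio and the G/C→A/T share (the alkylation
  signature of MNU: alkylated guanine mispairs with thymine, fixing G→A on the
  mutated strand and C→T on the other), per-plant mutation rates per Mb,
  100-kb window densities along chromosomes, and InDel size histograms.
- **Context bias**: base frequencies at ±20 bp around all mutated guanines
  versus a null of randomly sampled genomic G positions, reported as
  per-offset frequency differences (MNU prefers purines at −1).
- **Variant-effect annotation** written from scratch against longest-isoform
  gene models: strand-aware codon translation under the standard genetic code
  (missense / synonymous / stop gained / stop lost / start lost), the two
  canonical intronic splice bases, UTRs, introns, 5-kb upstream/downstream
  windows, intergenic — with the usual HIGH/MODERATE/LOW/MODIFIER impact
  tiers and per-category gene-coverage summaries.
- **Library reports**: a gene-keyed TILLING index with impact-filtered
  queries, M1→M2 transmission summaries from validation tables, the Pearson
  correlation between mutational load and seed-setting percentage, and
  cohort-size extrapolation — linear (n = n_obs · target/observed) and
  Poisson (coverage = 1 − e^(−λn)) — answering "how many plants until every
  gene carries a knockout candidate?"
- A **synthetic cohort simulator** that emits a joint VCF plus truth,
  phenotype and validation tables with the same statistical structure
  (spectrum, context bias, per-plant load, call noise, phenotype coupling,
  transmission loss), so the whole pipeline is testable without any
  sequencing data.

## Worked example

Simulate a small 5-plant cohort on a 1 Mb toy genome, curate it, and summarize:

```python
import numpy as np
from mnucohort import *

cfg = CohortSimConfig.toy(n_plants=5)          # study-condition defaults, small genome
rng = np.random.default_rng(7)
genome, genes, mask = simulate_genome(cfg, rng)
cohort = simulate_cohort(cfg, genome, genes, mask, rng)

curated, summary = curate(cohort.records, cohort.plant_ids, cohort.mask,
                          qv_threshold=80.0)
spec = compute_spectrum([v for v in curated if v.is_snv])
print(f"Ts/Tv = {spec.ts_tv_ratio:.2f} ({spec.ts_count}/{spec.tv_count})")
print(f"G/C->A/T fraction = {100 * spec.gc_to_at_fraction:.1f}%")
```

prints

```
Ts/Tv = 10.26 (1795/175)
G/C->A/T fraction = 88.2%
```

The curated set keeps 1,980 of 2,178 emitted calls. The Ts/Tv of the curated
set sits below the configured 14.81 because false-positive calls with QV just
above 80 survive the threshold and their substitution classes are random —
exactly the contamination the QV calibration quantifies. Effect annotation and
the extrapolation helpers continue from the same objects:

```python
anns = annotate_variants(curated, genes, cohort.genome)
print(summarize_gene_coverage(anns, n_annotated_genes=len(genes)))

est = saturation_estimate(0.086, 266, target_fraction=1.0, model="linear")
print(f"{est.estimated_n:.0f} plants for full coverage")   # -> 3093
```

The same steps are available as shell subcommands (`mnucohort simulate`,
`curate`, `calibrate`, `spectrum`, `density`, `indels`, `context`, `annotate`,
`effects-summary`, `tilling`, `transmission`, `correlate`, `saturate`); run
`mnucohort --help` for the catalogue.

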