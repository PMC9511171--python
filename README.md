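# haplopanel

Haplotype characterization of candidate-gene and QTL regions in germplasm
panels, with minimum discriminating SNP-set selection, cross-panel haplotype
surveys, KASP assay context extraction, and haplotype/SNP–phenotype
association — the workflow an applied cereal-breeding program uses to turn a
mapped grain-shape locus into a deployable trait marker.

## Who this is for

Breeders and quantitative geneticists who have a gene or QTL region (for
example the rice grain-length loci *GS3* on chr3 and a QTL near *GL7* on
chr7), genotype matrices for that region from a resequencing panel or SNP
array, and phenotypes, and who want to:

1. filter the region's SNPs and samples on missingness and minor allele
   frequency;
2. partition samples into **haplotype groups** — a haplotype is the vector of
   alleles across all retained SNPs, and two samples share a haplotype iff
   their vectors are identical;
3. find a **minimum SNP set**: the smallest SNP subset whose alleles differ
   between every pair of named haplotype groups, so that a handful of cheap
   single-SNP assays can classify any new panel;
4. survey those tag SNPs across other germplasm and quantify how
   haplotype/SNP classes explain a phenotype.

## The statistics at the core

* **Filtering cascade** (fixed order, strict comparators): heterozygous
  calls → missing (inbred germplasm convention); drop SNPs with missing
  fraction > *m*₁; drop samples with missing fraction > *m*₂ over the
  surviving SNPs; drop SNPs with MAF < *f* over the surviving samples'
  non-missing calls; optionally drop monomorphic SNPs. Two presets bundle
  published threshold regimes: `3krgp` (0.2 / 0.2 / 0.001) and `hdra-us`
  (0.15 / 0.2 / 0.02 + monomorphic).
* **Haplotype grouping**: exact vector identity for complete-call samples;
  groups at or above the rare threshold are named Hap1, Hap2, … by
  descending size; samples with missing calls are assigned only when
  compatible with exactly one named group, otherwise Unclassified (or Rare
  when compatible only with a rare vector).
* **Minimum SNP set**: a set-cover problem over group pairs. SNPs inducing
  the same bipartition of the groups collapse into equivalence classes;
  an increasing-cardinality exact search guarantees minimality (verified in
  tests against independent brute-force enumeration), with a greedy
  fallback for very large instances. Any discriminating set of biallelic
  SNPs obeys `size ≥ ceil(log2 n_groups)`.
* **Association**: one-way fixed-effects ANOVA of a phenotype against a
  classification, with `PVE = 100 · SS_between / SS_total` (the R² of the
  classification) and Tukey-HSD compact letter display. Two-locus analyses
  use the four homozygous classes (Class1 = long/long … Class4 =
  medium/medium) for inbred lines and all nine genotype classes for
  segregating populations, from which gene action (e.g. a recessive
  long-grain allele) is read off het-vs-homozygote contrasts.

A synthetic-panel generator (`haplopanel.synthetic_data`) emulates the data
regime this analysis assumes — subpopulation-skewed haplotype frequencies
across eight rice subpopulations, rare perturbed haplotypes, heterozygous
and missing call noise, and a two-locus grain-length model with a recessive
long allele at the major locus — so the whole pipeline is testable without
any external download.

## Worked example

```python
import haplopanel as hp
from haplopanel.filtering import FilterParams, apply_cascade
from haplopanel.haplotyping import RareRule, characterize, coverage_percent
from haplopanel.tagsnp import minimum_tag_set
from haplopanel.association import anova_pve

spec = hp.grain_length_preset(n_samples=2000, seed=1)
panel = hp.synthetic_data.generate_panel(spec)

filtered, report = apply_cascade(panel.matrices["GS3"], FilterParams.preset("3krgp"))
part = characterize(filtered, RareRule("min_frequency", 0.012))
print([(g.label, g.member_count) for g in part.groups])
print("coverage:", coverage_percent(part.n_classified, part.n_samples), "%")

tags = minimum_tag_set(part.groups, part.variants, mode="auto")
print("minimum SNP set:", tags.snp_ids, f"({tags.method})")

classes = {s: g for s, g in part.assignments.items() if g.startswith("Hap")}
res = anova_pve(panel.phenotypes, classes, alpha=0.001)
print(f"F = {res.f_stat:.1f}, p = {res.p_value:.3g}, PVE = {res.pve:.1f}%")
```

prints

```
[('Hap1', 675), ('Hap2', 308), ('Hap3', 259), ('Hap4', 245), ('Hap5', 230), ('Hap6', 87), ('Hap7', 84), ('Hap8', 71)]
coverage: 99 %
minimum SNP set: ['GS3_02', 'GS3_03', 'GS3_05'] (exact)
F = 622.0, p = 0, PVE = 69.1%
```

Eight haplotype groups describe 99% of the 1,973 samples surviving the
cascade; three SNPs suffice to tell the eight groups apart; and the group
labels alone explain ~69% of grain-length variance — Hap1, the only group
carrying the long allele at the functional SNP, averages ~7.1 mm against
~6.2 mm for the medium-grain groups.

The same stages are available from the shell:

```bash
haplopanel simulate --n 2000 --seed 1 --out sim/
haplopanel pipeline --genotypes sim/GS3.vcf --meta sim/meta.tsv \
    --pheno sim/pheno.tsv --preset 3krgp \
    --rare-mode min_frequency --rare-threshold 0.012 --out run/
```

which writes `filter_report.tsv`, `haplotypes.tsv`, `groups.tsv`,
`tagset.tsv`, `survey.tsv`, `association.tsv` and a run manifest into
`run/`.

## Layout

```
src/haplopanel/
  core.py            sample × SNP call matrix, variants, metadata types
  io_formats.py      VCF / snp_table / phenotype / metadata / report I/O
  filtering.py       missingness + MAF cascade with audit trail
  haplotyping.py     grouping, rare rule, surveys, composition summaries
  tagsnp.py          exact + greedy minimum discriminating SNP sets
  association.py     ANOVA/PVE, Tukey letters, two-locus gene action
  assay_design.py    KASP flank extraction from an indexed FASTA
  synthetic_data.py  calibrated panel and cross-population generators
  cli.py             `haplopanel` subcommands with run manifests
```

See `docs/methods.md` for the model, parameter choices, and limitations.
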