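# Methods

This note records the models, conventions and numerical choices behind
`haplopanel`, in the order the pipeline runs.

## Genotype representation

Calls are unphased diploid genotypes collapsed to four states — homozygous
reference, homozygous alternate, heterozygous, missing — stored as an
`int8` sample × SNP matrix. The pipeline targets inbred (near-homozygous)
germplasm: heterozygous calls are treated as genotyping noise and recoded
to missing by the standard presets rather than phased. Only biallelic SNPs
enter the matrix; multi-allelic records and indels are dropped at read time
with logged counts, because haplotype vectors and minor allele frequency
are defined for two alleles. Coordinates are 1-based and inclusive,
matching rice IRGSP v1 positions; VCF positions are kept as-is.

The `snp_table` dialect (tab-separated, first column sample id, header of
marker ids, cells `CC` / `CA` / `C` / `N`) mirrors portal-style genotype
exports whose exact format is not standardized. Optional `##variant`
comment lines pin id/chrom/pos/ref/alt per marker, which makes the
VCF ↔ snp_table round trip exact; without them the majority base of each
column is taken as the reference allele.

## Filtering cascade

Five stages in fixed order, all comparators strict (a SNP *at* the
threshold survives):

1. heterozygous → missing (`het_as_missing`);
2. drop SNPs with missing fraction > `snp_missing_max` over all current
   samples;
3. drop samples with missing fraction > `sample_missing_max` over the SNPs
   surviving stage 2;
4. drop SNPs with MAF < `maf_min`, MAF computed over non-missing calls of
   the surviving samples (heterozygous calls never contribute; a column
   left with no observed call counts as MAF 0 here);
5. optionally drop monomorphic SNPs (MAF exactly 0). With `maf_min > 0`
   monomorphic SNPs already fall out at stage 4; the explicit stage exists
   for the array-panel parameterization and for reporting clarity.

The order is part of the contract: removing high-missingness samples
changes the MAF denominator, and the test suite contains a fixture where
swapping stages 3 and 4 changes the surviving SNP set. A consequence worth
knowing: the cascade is a *single pass*, not a universal fixed point. When
stage 4 removes a SNP, a sample that sat exactly on the stage-3 boundary
has a smaller denominator on a second pass and can then be dropped. At
realistic missingness (a few percent, thresholds at 15–20%) this never
happens — idempotence is verified on generated panels — and the boundary
counterexample is frozen as a regression test documenting the behavior.

Presets: `3krgp` (het→missing, 0.2, 0.2, MAF 0.001, resequencing-panel
regime) and `hdra-us` (0.15, 0.2, MAF 0.02 plus monomorphic drop,
array/U.S.-panel regime). Each preset also carries a rare-haplotype rule
(below). A full audit trail attributes every dropped SNP and sample to
exactly one stage.

## Haplotype grouping

A haplotype is the allele vector over all retained SNPs of the region;
grouping is exact vector identity over complete-call samples. The rare
rule has two forms: `min_count` (names groups with at least *k* members;
strictly fewer is rare) and `min_frequency` (at least a fraction *q* of the
filtered panel, inclusive). The count and frequency forms correspond at a
given panel size (30 of ~2,400 ≈ 0.012); analyses on generated panels use
the frequency form, `q = 0.012`, because it transfers across panel sizes.

Samples with missing calls are assigned to a named group only when their
observed calls are compatible with exactly one named group's vector;
compatibility with two or more named groups, or with none, sends them to
Unclassified, and compatibility with only a rare vector sends them to
Rare. Rare status is decided from complete-call counts *before*
partial-match assignment, so partial samples never lift a rare vector over
the threshold. After assignment, labels Hap1…HapN are ordered by final
member count (ties broken by lexicographic allele vector, reference allele
first) so Hap1 is always the most common group; the ordering is
deterministic under sample permutation.

Survey mode applies a reference panel's named groups to another panel
genotyped only at tag SNPs. Any heterozygous or missing call at a tag SNP
makes the sample Unclassified; a complete vector matching no reference
group is reported as Novel with its vector rather than silently creating a
group. Two reference groups that collide on the provided SNPs are a
configuration error. Coverage percentages are reported as integers,
rounded half-up.

Composition summaries roll subpopulations into varietal groups
(Indica = indica, aus, indica-admix; Japonica = tropical-japonica,
temperate-japonica, aromatic, japonica-admix; the rest Admix/Unknown).

## Minimum discriminating SNP set

A SNP separates a group pair when its alleles differ between them; a set is
discriminating when every unordered pair is separated by at least one
member. Selection works on SNP *equivalence classes* — SNPs inducing the
same bipartition of the groups are interchangeable — which keeps the exact
search tractable at candidate-gene scale (tens of SNPs, ≤ 10 groups).
Exact mode enumerates class subsets by increasing cardinality and returns
the first covering subset, which is minimum by construction; tests verify
equality with an independent brute-force enumeration on hundreds of random
instances. Greedy mode repeatedly adds the class covering the most
outstanding pairs; it can exceed the minimum (a frozen 5-group fixture
needs 3 exact vs 4 greedy) and is used automatically only when the exact
search would exceed its subset budget (2·10⁶ subsets), with the
`ceil(log2 n_groups)` lower bound logged alongside the upper bound.

Ties are broken toward the lowest genomic position (then lexicographic id)
— deterministic, and position-stable assays are what a breeder orders. A
caller-supplied priority list (e.g. a known functional mutation) is
honored among otherwise equivalent SNPs only.

## Association and gene action

`anova_pve` fits a one-way fixed-effects classification after averaging
replicate (multi-environment) phenotype records per line — the line, not
the plot, is the experimental unit. PVE is reported as the plain R² of the
classification (100·SS_between/SS_total), not adjusted. Per-class letters
come from Tukey HSD all-pairs tests at the stated alpha, rendered with the
insert-and-absorb compact letter display; Tukey is the conventional choice
for all-pairs letters. Classes with a single phenotyped sample stay in the
mean table but are excluded from letters. Degenerate inputs are handled
explicitly: zero within-class variance with differing means gives p = 0
and distinct letters; zero total variance gives PVE 0.

Two-locus analyses: the four-class scheme (Class1 long/long, Class2
long/medium, Class3 medium/long, Class4 medium/medium) uses homozygous
samples only and drops heterozygotes with a logged count, matching inbred
panels; the nine-class scheme keeps all 3×3 allele configurations for
segregating populations. Gene action is read from Welch t contrasts of the
heterozygous class against each homozygous class within every fixed state
of the other locus: het ≈ homo-medium together with homo-long > het reads
as a recessive long allele; both contrasts significant reads as additive;
neither, as insufficient evidence. Contrasts with an empty or singleton
operand class are marked not estimable.

## KASP flank extraction

Assay context is the forward-strand reference sequence: `flank` bases
upstream, `[REF/ALT]`, `flank` bases downstream (default 100 bp each side,
total 2·flank+5 characters for single-base alleles). Requests within
`flank` of a contig edge are boundary errors — no padding — and a
disagreement between the reference base and the declared ref allele is a
consistency error. No primer design or thermodynamics is attempted.

## Synthetic panel generator

The generator emulates the structure this analysis assumes in diversity
panels, with all randomness from one seeded `numpy` generator (same seed ⇒
byte-identical outputs):

* per-sample subpopulation from a fixed mix of eight rice subpopulations
  (Indica-group subpopulations ~53%, japonica groups ~35%, admixed the
  rest);
* per region, a haplotype drawn from that subpopulation's frequency table.
  The calibrated preset has two regions: a *GS3*-like gene (12 SNPs, 8
  haplotypes; Hap1 alone carries the long allele at the functional SNP and
  dominates tropical japonica at 76%, Hap3 dominates temperate japonica)
  and a *qGL7.1*-like QTL interval (10 SNPs, 9 haplotypes; the long allele
  marks three haplotypes, one dominant in indica and one in tropical
  japonica);
* with probability `rare_haplotype_rate` (default 0.01) the vector is
  replaced by a single-position flip of a common haplotype, guaranteed
  distinct from every defined vector;
* heterozygous noise (default 0.01 per call) is injected before missing
  noise (default 0.03 per call), so a call can end missing regardless of
  het status;
* grain length (mm) = μ + a_A·[long at region A] + a_B·[long at region B]
  + N(0, σ), with defaults μ = 6.0, a_A = 0.9, a_B = 0.3, σ = 0.25. These
  place the homozygous two-locus class means at 7.2 / 6.9 / 6.3 / 6.0 mm
  with the major locus clearly stronger, and put the PVE of a two-locus
  classification near 78% and of single-region haplotype groups near
  70–75%. Panel samples are homozygous in truth, as inbred germplasm is;
  dominance (`recessive-long` at region A by default) matters only in the
  companion cross-population generator, which draws 1:2:1 genotypes at the
  two functional SNPs and applies the stated gene action (recessive-long:
  heterozygote contributes nothing; additive: half effect).

Problem sizes were scaled to desk scale deliberately: 12 and 10 SNPs per
region rather than the ~70–170 of a resequencing export, and 2,000-sample
panels. Group structure, noise layering and effect sizes — not raw
dimensions — are what the pipeline's correctness depends on.

What the generator does **not** emulate: linkage disequilibrium decay or
recombination within a region (haplotypes are atomic, which matches the
haplotype definition used), genotyping batch effects, pedigree structure,
and genuine multi-environment G×E. Passing recovery tests therefore shows
the pipeline's logic is correct under the stated noise model, not that any
particular real panel will yield the same group counts or PVE.

## Numerical conventions

* Strict inequalities throughout the cascade; inclusive rare-frequency
  threshold (`≥`).
* MAF denominator: non-missing homozygous calls only.
* Coverage percent: half-up integer rounding.
* Tie-breaks: descending member count then lexicographic vector for group
  labels; lowest genomic position for tag SNPs.
* Determinism: no global RNG state anywhere; CLI result tables contain no
  timestamps (only the run manifest does), so reruns are byte-identical.

## Known limitations

* Exact tag-set search is exponential in the number of SNP equivalence
  classes; beyond the subset budget the result is greedy and only an upper
  bound on the minimum (flagged in the output).
* Partial-match assignment trusts the named vectors; a sample missing
  exactly the SNPs that distinguish two named groups is Unclassified even
  if one group is overwhelmingly more frequent (no probabilistic
  assignment, by design).
* The ANOVA is a plain one-way fit: no kinship or population-structure
  correction, so PVE on structured panels measures association, not
  causal effect size.
* No imputation, phasing, LD pruning or Hardy–Weinberg filtering — out of
  scope for this workflow.
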