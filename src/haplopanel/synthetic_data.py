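"""Synthetic germplasm-panel generator.

Emulates the statistical structure the pipeline assumes in real panels:
subpopulation-skewed haplotype frequencies in one or more gene regions,
a small rate of rare (single-position-perturbed) haplotypes, per-call
heterozygous and missing noise, and a two-locus additive phenotype keyed on
a functional SNP per region, with optional recessivity of the long allele
at locus A. A ground-truth record accompanies every panel so recovery can
be scored exactly.

All randomness flows from a single seed through one
:class:`numpy.random.Generator`; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ALT, HET, MISSING, REF, SampleMeta, Variant, VariantMatrix
from .errors import HaplopanelError

RARE_LABEL = "RARE"

#: Subpopulation mix loosely shaped like a global rice diversity panel:
#: Indica-group subpopulations dominate, tropical/temperate japonica follow.
DEFAULT_SUBPOP_PROPORTIONS = {
    "indica": 0.40,
    "indica-admix": 0.06,
    "aus": 0.07,
    "tropical-japonica": 0.15,
    "temperate-japonica": 0.12,
    "japonica-admix": 0.05,
    "aromatic": 0.03,
    "admix": 0.12,
}


@dataclass(frozen=True)
class RegionSpec:
    """One gene/QTL region: its SNPs, haplotypes, and subpopulation skew.

    ``haplotypes`` maps label -> binary string over the region's SNPs
    ('0' = ref allele, '1' = alt allele). ``subpop_freqs`` maps
    subpopulation -> {label: frequency}, each summing to 1.
    ``functional_snp``/``long_allele`` designate the SNP and base that
    confer the long-grain class for the phenotype model.
    """

    name: str
    variants: tuple[Variant, ...]
    haplotypes: dict[str, str]
    subpop_freqs: dict[str, dict[str, float]]
    functional_snp: str
    long_allele: str

    def validate(self) -> None:
        m = len(self.variants)
        vectors = set()
        for label, bits in self.haplotypes.items():
            if len(bits) != m or set(bits) - {"0", "1"}:
                raise HaplopanelError(
                    f"region {self.name}: haplotype {label} must be a binary "
                    f"string of length {m}"
                )
            if bits in vectors:
                raise HaplopanelError(
                    f"region {self.name}: duplicate haplotype vector for {label}"
                )
            vectors.add(bits)
        for subpop, freqs in self.subpop_freqs.items():
            unknown = set(freqs) - set(self.haplotypes)
            if unknown:
                raise HaplopanelError(
                    f"region {self.name}: subpop {subpop} references unknown "
                    f"haplotypes {sorted(unknown)}"
                )
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise HaplopanelError(
                    f"region {self.name}: subpop {subpop} haplotype frequencies "
                    f"sum to {total}, not 1"
                )
        ids = [v.id for v in self.variants]
        if self.functional_snp not in ids:
            raise HaplopanelError(
                f"region {self.name}: functional SNP {self.functional_snp} not "
                "among the region's variants"
            )
        v = self.variants[ids.index(self.functional_snp)]
        if self.long_allele not in (v.ref_allele, v.alt_allele):
            raise HaplopanelError(
                f"region {self.name}: long allele {self.long_allele} matches "
                f"neither allele of {self.functional_snp}"
            )

    def functional_index(self) -> int:
        return [v.id for v in self.variants].index(self.functional_snp)

    def long_is_alt(self) -> bool:
        return self.long_allele == self.variants[self.functional_index()].alt_allele

    def vector_codes(self, label: str) -> np.ndarray:
        return np.array([int(b) for b in self.haplotypes[label]], dtype=np.int8)

    def is_long(self, vector: np.ndarray) -> bool:
        allele = int(vector[self.functional_index()])
        return (allele == ALT) == self.long_is_alt()


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Full parameterization of a simulated germplasm panel.

    Phenotype model: grain length (mm) = ``mu`` + ``effect_a`` if the sample
    carries the long haplotype class at the first region + ``effect_b``
    likewise at the second region + Normal(0, ``sigma``). ``dominance_a``
    ("recessive-long" or "additive") only matters for heterozygous
    genotypes, i.e. in cross populations; panel samples are homozygous in
    truth, as expected for inbred germplasm.
    """

    regions: tuple[RegionSpec, ...]
    n_samples: int = 2000
    subpop_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBPOP_PROPORTIONS)
    )
    rare_haplotype_rate: float = 0.01
    missing_rate: float = 0.03
    het_rate: float = 0.01
    mu: float = 6.0
    effect_a: float = 0.9
    effect_b: float = 0.3
    dominance_a: str = "recessive-long"
    sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise HaplopanelError("n_samples must be >= 1")
        total = sum(self.subpop_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise HaplopanelError(f"subpop proportions sum to {total}, not 1")
        for rate, name in (
            (self.rare_haplotype_rate, "rare_haplotype_rate"),
            (self.missing_rate, "missing_rate"),
            (self.het_rate, "het_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise HaplopanelError(f"{name} must be in [0, 1]")
        if self.dominance_a not in ("recessive-long", "additive"):
            raise HaplopanelError(f"unknown dominance mode {self.dominance_a!r}")
        if self.sigma < 0:
            raise HaplopanelError("sigma must be non-negative")
        if not self.regions:
            raise HaplopanelError("at least one region is required")
        for region in self.regions:
            region.validate()
            for subpop in self.subpop_proportions:
                if subpop not in region.subpop_freqs:
                    raise HaplopanelError(
                        f"region {region.name}: no haplotype frequencies for "
                        f"subpopulation {subpop}"
                    )


@dataclass
class SyntheticPanel:
    """Generated panel plus its ground truth."""

    matrices: dict[str, VariantMatrix]
    meta: list[SampleMeta]
    phenotypes: pd.DataFrame
    truth: pd.DataFrame  # per sample: subpop, per-region label, classes, genetic value
    spec: SyntheticPanelSpec


def _perturbed_vector(
    rng: np.random.Generator, region: RegionSpec, base_label: str
) -> np.ndarray:
    """A rare haplotype: one-position flip of a common vector, guaranteed
    distinct from every defined haplotype."""
    defined = {region.haplotypes[l] for l in region.haplotypes}
    base = region.vector_codes(base_label)
    positions = rng.permutation(len(base))
    for pos in positions:
        vec = base.copy()
        vec[pos] = 1 - vec[pos]
        if "".join(str(int(b)) for b in vec) not in defined:
            return vec
    raise HaplopanelError(
        f"region {region.name}: cannot perturb {base_label} into a novel vector"
    )


def generate_panel(spec: SyntheticPanelSpec) -> SyntheticPanel:
    """Generate a panel per the spec.

    Sampling order per sample: subpopulation, then one haplotype per region
    from that subpopulation's frequencies (replaced, with probability
    ``rare_haplotype_rate``, by a perturbed rare vector), then per-call HET
    injection, then per-call MISSING injection, then the phenotype draw.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i + 1:05d}" for i in range(n)]

    subpops = list(spec.subpop_proportions)
    probs = np.array([spec.subpop_proportions[s] for s in subpops], dtype=float)
    probs = probs / probs.sum()
    subpop_draw = rng.choice(len(subpops), size=n, p=probs)
    sample_subpop = [subpops[k] for k in subpop_draw]

    matrices: dict[str, VariantMatrix] = {}
    truth_cols: dict[str, list] = {"sample_id": samples, "subpopulation": sample_subpop}
    region_long: dict[str, np.ndarray] = {}

    for region in spec.regions:
        labels = list(region.haplotypes)
        calls = np.empty((n, len(region.variants)), dtype=np.int8)
        true_labels: list[str] = []
        is_long = np.zeros(n, dtype=bool)
        for i in range(n):
            freqs = region.subpop_freqs[sample_subpop[i]]
            weights = np.array([freqs.get(l, 0.0) for l in labels], dtype=float)
            weights = weights / weights.sum()
            label = labels[int(rng.choice(len(labels), p=weights))]
            if spec.rare_haplotype_rate > 0 and rng.random() < spec.rare_haplotype_rate:
                vector = _perturbed_vector(rng, region, label)
                true_labels.append(RARE_LABEL)
            else:
                vector = region.vector_codes(label)
                true_labels.append(label)
            calls[i, :] = vector
            is_long[i] = region.is_long(vector)
        # noise layering: HET first, then MISSING may overwrite either state
        if spec.het_rate > 0:
            calls[rng.random(calls.shape) < spec.het_rate] = HET
        if spec.missing_rate > 0:
            calls[rng.random(calls.shape) < spec.missing_rate] = MISSING
        matrices[region.name] = VariantMatrix(
            list(samples), list(region.variants), calls
        )
        truth_cols[f"hap_{region.name}"] = true_labels
        truth_cols[f"long_{region.name}"] = is_long.tolist()
        region_long[region.name] = is_long

    names = [r.name for r in spec.regions]
    long_a = region_long[names[0]]
    long_b = region_long[names[1]] if len(names) > 1 else np.zeros(n, dtype=bool)
    genetic = spec.mu + spec.effect_a * long_a + spec.effect_b * long_b
    noise = rng.normal(0.0, spec.sigma, size=n) if spec.sigma > 0 else np.zeros(n)
    values = genetic + noise
    truth_cols["genetic_value"] = genetic.tolist()

    phenotypes = pd.DataFrame(
        {
            "sample_id": samples,
            "trait": "grain_length",
            "environment": "Y1",
            "value": values,
        }
    )

    years = rng.integers(1981, 2021, size=n)
    meta = [
        SampleMeta(
            sample_id=samples[i],
            subpopulation=sample_subpop[i],
            grain_class="long" if long_a[i] else "medium",
            release_year=int(years[i]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(truth_cols)
    return SyntheticPanel(
        matrices=matrices, meta=meta, phenotypes=phenotypes, truth=truth, spec=spec
    )


def _state_value(state: str, effect: float, dominance: str) -> float:
    """Genetic contribution of one locus given its genotype state."""
    if state == "homo-L":
        return effect
    if state == "homo-M":
        return 0.0
    return 0.0 if dominance == "recessive-long" else effect / 2.0


def generate_cross_population(
    region_a: RegionSpec,
    region_b: RegionSpec,
    n: int = 600,
    mu: float = 6.4,
    effect_a: float = 0.6,
    effect_b: float = 0.25,
    dominance_a: str = "recessive-long",
    dominance_b: str = "additive",
    sigma: float = 0.15,
    seed: int = 0,
    genotype_freqs: tuple[float, float, float] = (0.25, 0.5, 0.25),
) -> tuple[VariantMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a biparental segregating population at the two trait SNPs.

    Each line draws an independent genotype (homo-L / het / homo-M, default
    F2 proportions 1:2:1) at each region's functional SNP; the phenotype adds
    the two locus contributions with the stated gene action plus
    Normal(0, sigma) noise. Returns the two-SNP genotype matrix (with
    heterozygous calls), a phenotype table, and a truth table with the true
    nine-class label per line.
    """
    rng = np.random.default_rng(seed)
    samples = [f"L{i + 1:04d}" for i in range(n)]
    states = ("homo-L", "het", "homo-M")
    p = np.asarray(genotype_freqs, dtype=float)
    p = p / p.sum()

    variants = []
    calls = np.empty((n, 2), dtype=np.int8)
    state_cols = []
    for k, region in enumerate((region_a, region_b)):
        v = region.variants[region.functional_index()]
        variants.append(v)
        long_is_alt = region.long_is_alt()
        draw = rng.choice(3, size=n, p=p)
        col_states = [states[d] for d in draw]
        state_cols.append(col_states)
        for i, state in enumerate(col_states):
            if state == "het":
                calls[i, k] = HET
            elif (state == "homo-L") == long_is_alt:
                calls[i, k] = ALT
            else:
                calls[i, k] = REF

    genetic = np.array(
        [
            mu
            + _state_value(state_cols[0][i], effect_a, dominance_a)
            + _state_value(state_cols[1][i], effect_b, dominance_b)
            for i in range(n)
        ]
    )
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    matrix = VariantMatrix(samples, variants, calls)
    phenotypes = pd.DataFrame(
        {
            "sample_id": samples,
            "trait": "grain_length",
            "environment": "Y1",
            "value": genetic + noise,
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": samples,
            "state_a": state_cols[0],
            "state_b": state_cols[1],
            "genetic_value": genetic,
        }
    )
    return matrix, phenotypes, truth


def match_groups_to_truth(partition, region: RegionSpec) -> dict[str, str]:
    """Map recovered group labels to the region's defined haplotype labels.

    Matching is by allele vector restricted to the partition's surviving
    SNPs (labels assigned by descending size need not coincide with the
    defined labels when sampling reorders group sizes). Unmatched recovered
    groups are absent from the result.
    """
    region_ids = [v.id for v in region.variants]
    keep = [region_ids.index(v.id) for v in partition.variants]
    defined = {
        tuple(int(b) for b in region.vector_codes(label)[keep]): label
        for label in region.haplotypes
    }
    mapping = {}
    for group in partition.groups:
        truth_label = defined.get(tuple(int(a) for a in group.alleles))
        if truth_label is not None:
            mapping[group.label] = truth_label
    return mapping


# ---------------------------------------------------------------------------
# calibrated preset
# ---------------------------------------------------------------------------

def _region_a() -> RegionSpec:
    """GS3-like region: 12 SNPs, 8 haplotypes; Hap1 alone carries the long
    allele at the functional SNP and dominates tropical japonica, Hap3
    dominates temperate japonica."""
    positions = [
        16729650, 16730210, 16730845, 16731402, 16732076, 16732655,
        16733441, 16733890, 16734220, 16734560, 16734890, 16735100,
    ]
    refs = ["G", "T", "A", "C", "G", "A", "C", "T", "G", "C", "A", "T"]
    alts = ["A", "C", "G", "T", "A", "G", "A", "C", "A", "T", "G", "C"]
    variants = tuple(
        Variant(
            id="GS3-SNP1" if pos == 16733441 else f"GS3_{k + 1:02d}",
            chrom="chr3",
            pos=pos,
            ref_allele=refs[k],
            alt_allele=alts[k],
        )
        for k, pos in enumerate(positions)
    )
    # bit 6 (0-based) is the functional SNP; only Hap1 carries the alt there
    haplotypes = {
        "Hap1": "000000100000",
        "Hap2": "010101000101",
        "Hap3": "001100010011",
        "Hap4": "011011000110",
        "Hap5": "000011010000",
        "Hap6": "010110001101",
        "Hap7": "001111001100",
        "Hap8": "111000011010",
    }
    subpop_freqs = {
        "tropical-japonica": {"Hap1": 0.76, "Hap3": 0.12, "Hap2": 0.04, "Hap6": 0.03, "Hap8": 0.05},
        "temperate-japonica": {"Hap3": 0.46, "Hap1": 0.20, "Hap6": 0.14, "Hap8": 0.20},
        "indica": {"Hap1": 0.30, "Hap2": 0.25, "Hap4": 0.20, "Hap5": 0.15, "Hap7": 0.10},
        "aus": {"Hap5": 0.45, "Hap4": 0.30, "Hap2": 0.15, "Hap7": 0.10},
        "aromatic": {"Hap3": 0.40, "Hap6": 0.30, "Hap1": 0.30},
        "indica-admix": {"Hap1": 0.35, "Hap2": 0.25, "Hap4": 0.20, "Hap5": 0.20},
        "japonica-admix": {"Hap1": 0.45, "Hap3": 0.35, "Hap6": 0.20},
        "admix": {"Hap1": 0.40, "Hap2": 0.20, "Hap3": 0.20, "Hap4": 0.10, "Hap5": 0.05, "Hap8": 0.05},
    }
    return RegionSpec(
        name="GS3",
        variants=variants,
        haplotypes=haplotypes,
        subpop_freqs=subpop_freqs,
        functional_snp="GS3-SNP1",
        long_allele="A",
    )


def _region_b() -> RegionSpec:
    """qGL7.1-like region: 10 SNPs, 9 haplotypes; the functional SNP's G
    (alt) allele marks long-grain haplotypes (Hap1/Hap2/Hap6)."""
    positions = [
        24845100, 24901220, 24957800, 25014500, 25071300,
        25128200, 25211630, 25254900, 25287400, 25319700,
    ]
    refs = ["C", "G", "T", "A", "C", "G", "A", "T", "C", "G"]
    alts = ["T", "A", "C", "G", "T", "A", "G", "C", "T", "A"]
    variants = tuple(
        Variant(
            id="qGL7.1-SNP1" if pos == 25211630 else f"qGL71_{k + 1:02d}",
            chrom="chr7",
            pos=pos,
            ref_allele=refs[k],
            alt_allele=alts[k],
        )
        for k, pos in enumerate(positions)
    )
    haplotypes = {
        "Hap1": "0000001000",
        "Hap2": "1011001000",
        "Hap3": "0000000011",
        "Hap4": "0110000000",
        "Hap5": "0001100110",
        "Hap6": "1100111000",
        "Hap7": "0010100010",
        "Hap8": "0000010111",
        "Hap9": "0101010101",
    }
    subpop_freqs = {
        "indica": {"Hap1": 0.55, "Hap4": 0.15, "Hap5": 0.12, "Hap7": 0.10, "Hap8": 0.08},
        "aus": {"Hap1": 0.40, "Hap5": 0.20, "Hap8": 0.20, "Hap9": 0.20},
        "tropical-japonica": {"Hap2": 0.93, "Hap3": 0.04, "Hap6": 0.03},
        "temperate-japonica": {"Hap3": 0.55, "Hap2": 0.25, "Hap6": 0.20},
        "aromatic": {"Hap2": 0.45, "Hap3": 0.20, "Hap9": 0.35},
        "indica-admix": {"Hap1": 0.50, "Hap4": 0.20, "Hap5": 0.15, "Hap7": 0.15},
        "japonica-admix": {"Hap2": 0.60, "Hap3": 0.25, "Hap6": 0.15},
        "admix": {"Hap1": 0.35, "Hap2": 0.35, "Hap3": 0.15, "Hap9": 0.15},
    }
    return RegionSpec(
        name="qGL7.1",
        variants=variants,
        haplotypes=haplotypes,
        subpop_freqs=subpop_freqs,
        functional_snp="qGL7.1-SNP1",
        long_allele="G",
    )


def grain_length_preset(n_samples: int = 2000, seed: int = 0) -> SyntheticPanelSpec:
    """Calibrated two-region panel spec.

    Two regions with 8 and 9 haplotypes, strongly subpopulation-skewed
    frequencies, ~1% rare haplotypes, 3% missing and 1% heterozygous calls.
    The phenotype places the homozygous two-locus class means at
    7.2 / 6.9 / 6.3 / 6.0 mm (long/long ... medium/medium) with residual
    sd 0.25 mm, so the locus-A effect exceeds the locus-B effect.
    """
    spec = SyntheticPanelSpec(
        regions=(_region_a(), _region_b()),
        n_samples=n_samples,
        rare_haplotype_rate=0.01,
        missing_rate=0.03,
        het_rate=0.01,
        mu=6.0,
        effect_a=0.9,
        effect_b=0.3,
        dominance_a="recessive-long",
        sigma=0.25,
        seed=seed,
    )
    spec.validate()
    return spec
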