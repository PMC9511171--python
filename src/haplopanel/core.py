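"""Core domain types shared by every pipeline stage.

Allele calls are stored as a compact ``int8`` matrix (samples x variants).
Genotypes are unphased diploid calls collapsed to four states: homozygous
reference (REF), homozygous alternate (ALT), heterozygous (HET), and MISSING.
Germplasm panels of inbred lines are expected to be almost entirely
homozygous; HET calls are treated as noise and recoded to MISSING by the
standard filtering presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

# Allele-call codes. MISSING is negative so "call >= 0" selects observed calls.
REF: int = 0
ALT: int = 1
HET: int = 2
MISSING: int = -1

CALL_NAMES = {REF: "REF", ALT: "ALT", HET: "HET", MISSING: "MISSING"}

IUPAC_BASES = set("ACGT")

SUBPOPULATIONS = (
    "aus",
    "indica",
    "indica-admix",
    "japonica-admix",
    "tropical-japonica",
    "temperate-japonica",
    "aromatic",
    "admix",
    "unknown",
)

#: Varietal-group rollup used for composition summaries.
VARIETAL_GROUPS = {
    "aus": "Indica",
    "indica": "Indica",
    "indica-admix": "Indica",
    "tropical-japonica": "Japonica",
    "temperate-japonica": "Japonica",
    "aromatic": "Japonica",
    "japonica-admix": "Japonica",
    "admix": "Admix",
    "unknown": "Unknown",
}

GRAIN_CLASSES = ("long", "medium", "short", "unknown")

TRAITS = ("grain_length", "grain_width", "lwr")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with 1-based genomic coordinates.

    Coordinates follow the reference assembly convention of the source data
    (IRGSP v1 for rice); positions are 1-based and inclusive.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"variant {self.id}: ref and alt alleles are identical")
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele.upper() not in IUPAC_BASES:
                raise FormatError(
                    f"variant {self.id}: allele {allele!r} is not a single A/C/G/T base"
                )

    def base_for(self, call: int) -> str:
        """Base spelled by a REF/ALT call; '.' for anything else."""
        if call == REF:
            return self.ref_allele
        if call == ALT:
            return self.alt_allele
        return "."


@dataclass
class VariantMatrix:
    """Sample x SNP allele-call grid for one genomic region.

    ``calls[i, j]`` is the call of ``samples[i]`` at ``variants[j]``. Only
    biallelic SNPs enter this type: multi-allelic records and indels are
    dropped at read time.
    """

    samples: list[str]
    variants: list[Variant]
    calls: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise FormatError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids in VariantMatrix")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate variant ids in VariantMatrix")
        valid = {REF, ALT, HET, MISSING}
        observed = set(np.unique(self.calls).tolist()) if self.calls.size else set()
        if not observed <= valid:
            raise FormatError(f"invalid call codes present: {sorted(observed - valid)}")

    # -- dimensions ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx: Sequence[int]) -> "VariantMatrix":
        idx = list(idx)
        return VariantMatrix(
            [self.samples[i] for i in idx], list(self.variants), self.calls[idx, :]
        )

    def take_variants(self, idx: Sequence[int]) -> "VariantMatrix":
        idx = list(idx)
        return VariantMatrix(
            list(self.samples), [self.variants[i] for i in idx], self.calls[:, idx]
        )

    def subset_variants(self, variant_ids: Iterable[str]) -> "VariantMatrix":
        """Restrict to the given variant ids, in the given order."""
        return self.take_variants([self.variant_index(v) for v in variant_ids])

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame (samples x variant ids) of call codes."""
        return pd.DataFrame(self.calls, index=self.samples, columns=self.variant_ids)


@dataclass(frozen=True)
class SampleMeta:
    """Passport data for one germplasm accession."""

    sample_id: str
    subpopulation: str = "unknown"
    grain_class: str = "unknown"
    release_year: int | None = None

    def __post_init__(self):
        if self.subpopulation not in SUBPOPULATIONS:
            raise FormatError(
                f"sample {self.sample_id}: unknown subpopulation {self.subpopulation!r}"
            )
        if self.grain_class not in GRAIN_CLASSES:
            raise FormatError(
                f"sample {self.sample_id}: unknown grain class {self.grain_class!r}"
            )


def meta_by_id(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    out: dict[str, SampleMeta] = {}
    for m in meta:
        if m.sample_id in out:
            raise FormatError(f"duplicate sample id in metadata: {m.sample_id}")
        out[m.sample_id] = m
    return out


#: Column schema of a phenotype table (one row per sample/trait/environment).
PHENOTYPE_COLUMNS = ["sample_id", "trait", "environment", "value"]


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a phenotype DataFrame in place.

    Enforces the schema, positive values for length/width traits, and
    uniqueness of (sample, trait, environment).
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns: {missing}")
    df = df[PHENOTYPE_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    bad_trait = set(df["trait"]) - set(TRAITS)
    if bad_trait:
        raise FormatError(f"unknown traits in phenotype table: {sorted(bad_trait)}")
    df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
    nonpos = df[(df["trait"].isin(["grain_length", "grain_width"])) & (df["value"] <= 0)]
    if len(nonpos):
        raise FormatError(
            f"non-positive grain dimension for sample(s): "
            f"{sorted(nonpos['sample_id'].unique())}"
        )
    dup = df.duplicated(subset=["sample_id", "trait", "environment"])
    if dup.any():
        rows = df.loc[dup, "sample_id"].tolist()
        raise FormatError(f"duplicate (sample, trait, environment) rows: {rows}")
    return df.reset_index(drop=True)
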