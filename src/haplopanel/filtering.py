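"""SNP/sample filtering cascade for region genotype matrices.

The cascade runs in a fixed order:

1. recode heterozygous calls to missing (inbred-panel convention);
2. drop SNPs whose missing fraction exceeds ``snp_missing_max``;
3. drop samples whose missing fraction, over the surviving SNPs, exceeds
   ``sample_missing_max``;
4. drop SNPs whose minor allele frequency, over the surviving samples'
   non-missing calls, falls below ``maf_min``;
5. optionally drop monomorphic SNPs (MAF exactly 0).

All comparisons are strict: a SNP with missing fraction exactly at the
threshold is retained, and a SNP with MAF exactly at ``maf_min`` is
retained. The order matters — sample removal changes the denominator of the
MAF stage — and is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ALT, HET, MISSING, REF, VariantMatrix
from .errors import EmptyResultError, UndefinedMAFError

#: 3K-RGP-style preset: het→missing, SNP missing >0.2, sample missing >0.2,
#: MAF <0.001; monomorphic SNPs fall out of the MAF stage.
PRESET_3KRGP_PARAMS = dict(
    het_as_missing=True,
    snp_missing_max=0.2,
    sample_missing_max=0.2,
    maf_min=0.001,
    drop_monomorphic=False,
)

#: HDRA/U.S.-panel-style preset: SNP missing >0.15, sample missing >0.2,
#: MAF <0.02, monomorphic SNPs dropped explicitly.
PRESET_HDRA_US_PARAMS = dict(
    het_as_missing=True,
    snp_missing_max=0.15,
    sample_missing_max=0.2,
    maf_min=0.02,
    drop_monomorphic=True,
)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the filtering cascade."""

    het_as_missing: bool = True
    snp_missing_max: float = 0.2
    sample_missing_max: float = 0.2
    maf_min: float = 0.001
    drop_monomorphic: bool = False

    def __post_init__(self):
        if not 0.0 <= self.snp_missing_max <= 1.0:
            raise ValueError("snp_missing_max must be in [0, 1]")
        if not 0.0 <= self.sample_missing_max <= 1.0:
            raise ValueError("sample_missing_max must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")

    @classmethod
    def preset(cls, name: str) -> "FilterParams":
        if name == "3krgp":
            return cls(**PRESET_3KRGP_PARAMS)
        if name == "hdra-us":
            return cls(**PRESET_HDRA_US_PARAMS)
        raise ValueError(f"unknown filter preset {name!r} (expected '3krgp' or 'hdra-us')")


@dataclass
class StageRecord:
    stage: str
    snps_before: int
    snps_after: int
    samples_before: int
    samples_after: int
    dropped_snps: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Per-stage audit trail of the cascade."""

    stages: list[StageRecord] = field(default_factory=list)

    def record(self, stage: str, before: VariantMatrix, after: VariantMatrix) -> None:
        self.stages.append(
            StageRecord(
                stage=stage,
                snps_before=before.n_variants,
                snps_after=after.n_variants,
                samples_before=before.n_samples,
                samples_after=after.n_samples,
                dropped_snps=sorted(set(before.variant_ids) - set(after.variant_ids)),
                dropped_samples=sorted(set(before.samples) - set(after.samples)),
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "snps_before": s.snps_before,
                    "snps_after": s.snps_after,
                    "samples_before": s.samples_before,
                    "samples_after": s.samples_after,
                }
                for s in self.stages
            ]
        )


def minor_allele_frequency(calls: np.ndarray) -> float:
    """Minor allele frequency over the non-missing REF/ALT calls.

    Heterozygous calls never contribute (the cascade recodes them to missing
    before this stage; a stray HET in direct calls is ignored the same way).

    Raises
    ------
    UndefinedMAFError
        If no REF/ALT call is present.
    """
    calls = np.asarray(calls)
    n_ref = int(np.count_nonzero(calls == REF))
    n_alt = int(np.count_nonzero(calls == ALT))
    total = n_ref + n_alt
    if total == 0:
        raise UndefinedMAFError("MAF undefined: no non-missing homozygous calls")
    return min(n_ref, n_alt) / total


def _maf_column(calls: np.ndarray) -> float:
    """Column MAF for the cascade; an all-missing column counts as MAF 0."""
    try:
        return minor_allele_frequency(calls)
    except UndefinedMAFError:
        return 0.0


def apply_cascade(matrix: VariantMatrix, params: FilterParams) -> tuple[VariantMatrix, FilterReport]:
    """Run the five-stage filtering cascade.

    Returns the filtered matrix and a :class:`FilterReport` attributing every
    dropped SNP/sample to exactly one stage.

    Raises
    ------
    EmptyResultError
        If any stage removes all SNPs or all samples.
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise EmptyResultError("input", "samples" if matrix.n_samples == 0 else "SNPs")
    report = FilterReport()
    current = matrix

    # stage 1: het -> missing
    if params.het_as_missing:
        calls = current.calls.copy()
        calls[calls == HET] = MISSING
        recoded = VariantMatrix(list(current.samples), list(current.variants), calls)
        report.record("het_to_missing", current, recoded)
        current = recoded
    else:
        report.record("het_to_missing", current, current)

    # stage 2: SNP missingness over all current samples
    miss_frac = (current.calls == MISSING).mean(axis=0)
    keep = np.flatnonzero(miss_frac <= params.snp_missing_max)
    after = current.take_variants(keep)
    report.record("snp_missingness", current, after)
    if after.n_variants == 0:
        raise EmptyResultError("snp_missingness", "SNPs")
    current = after

    # stage 3: sample missingness over remaining SNPs
    miss_frac = (current.calls == MISSING).mean(axis=1)
    keep = np.flatnonzero(miss_frac <= params.sample_missing_max)
    after = current.take_samples(keep)
    report.record("sample_missingness", current, after)
    if after.n_samples == 0:
        raise EmptyResultError("sample_missingness", "samples")
    current = after

    # stage 4: minor allele frequency over remaining samples
    mafs = np.array([_maf_column(current.calls[:, j]) for j in range(current.n_variants)])
    keep = np.flatnonzero(mafs >= params.maf_min)
    after = current.take_variants(keep)
    report.record("maf", current, after)
    if after.n_variants == 0:
        raise EmptyResultError("maf", "SNPs")
    current = after

    # stage 5: monomorphic SNPs (explicit, for the HDRA-style parameterization)
    if params.drop_monomorphic:
        mafs = np.array(
            [_maf_column(current.calls[:, j]) for j in range(current.n_variants)]
        )
        keep = np.flatnonzero(mafs > 0.0)
        after = current.take_variants(keep)
        report.record("monomorphic", current, after)
        if after.n_variants == 0:
            raise EmptyResultError("monomorphic", "SNPs")
        current = after
    else:
        report.record("monomorphic", current, current)

    return current, report
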