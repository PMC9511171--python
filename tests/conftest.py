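"""Shared fixtures and matrix-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from haplopanel.core import ALT, HET, MISSING, REF, Variant, VariantMatrix

_CODE = {"0": REF, "1": ALT, "H": HET, ".": MISSING}

# Alternating ref/alt bases so neighbouring SNPs differ.
_REFS = "ACGT"
_ALTS = "GTAC"


def matrix_from_strings(rows: dict[str, str], chrom: str = "chr1",
                        start_pos: int = 100, step: int = 50) -> VariantMatrix:
    """Build a VariantMatrix from per-sample call strings.

    Characters: '0' ref call, '1' alt call, 'H' het, '.' missing.
    """
    n_snps = len(next(iter(rows.values())))
    variants = [
        Variant(
            f"snp{j + 1}", chrom, start_pos + j * step,
            _REFS[j % 4], _ALTS[j % 4],
        )
        for j in range(n_snps)
    ]
    samples = list(rows)
    calls = np.array(
        [[_CODE[c] for c in rows[s]] for s in samples], dtype=np.int8
    )
    return VariantMatrix(samples, variants, calls)


@pytest.fixture
def mk_matrix():
    return matrix_from_strings


def groups_from_strings(vectors: dict[str, str], counts: dict[str, int] | None = None):
    """Named haplotype groups from '0'/'1' allele strings."""
    from haplopanel.haplotyping import HaplotypeGroup

    return [
        HaplotypeGroup(
            label,
            np.array([_CODE[c] for c in bits], dtype=np.int8),
            (counts or {}).get(label, 1),
        )
        for label, bits in vectors.items()
    ]


def variants_for(n: int, chrom: str = "chr1", start: int = 100, step: int = 50):
    return [
        Variant(f"snp{j + 1}", chrom, start + j * step, _REFS[j % 4], _ALTS[j % 4])
        for j in range(n)
    ]
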