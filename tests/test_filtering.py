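"""Filtering cascade: stage order, strict boundaries, MAF, audit trail."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplopanel.core import MISSING, REF, ALT
from haplopanel.errors import EmptyResultError, UndefinedMAFError
from haplopanel.filtering import FilterParams, apply_cascade, minor_allele_frequency

from conftest import matrix_from_strings


@pytest.mark.parametrize(
    "calls, expected",
    [
        ([REF, REF, ALT, ALT], 0.5),
        ([REF] * 999 + [ALT], 0.001),
        ([REF, MISSING, MISSING, ALT, ALT], 1 / 3),
        ([ALT, ALT, ALT], 0.0),
    ],
)
def test_minor_allele_frequency(calls, expected):
    assert minor_allele_frequency(np.array(calls)) == pytest.approx(expected)


def test_maf_undefined_on_all_missing():
    with pytest.raises(UndefinedMAFError):
        minor_allele_frequency(np.array([MISSING, MISSING]))


def test_snp_missingness_boundary_is_kept():
    """A SNP with missing fraction exactly at the threshold survives."""
    m = matrix_from_strings({f"S{i}": v for i, v in enumerate("0101.")})
    filtered, _ = apply_cascade(
        m, FilterParams(snp_missing_max=0.2, sample_missing_max=1.0, maf_min=0.0)
    )
    assert filtered.n_variants == 1


def test_maf_threshold_is_strict():
    """MAF 0.1 < 0.2 drops; MAF exactly at maf_min is kept."""
    rows = {f"S{i}": "0" for i in range(9)}
    rows["S9"] = "1"
    m = matrix_from_strings(rows)
    with pytest.raises(EmptyResultError):
        apply_cascade(m, FilterParams(maf_min=0.2))
    filtered, _ = apply_cascade(m, FilterParams(maf_min=0.1))
    assert filtered.n_variants == 1


def test_all_het_snp_dropped_at_missingness_stage():
    """With het→missing, an all-HET SNP exceeds any missingness bound."""
    rows = {f"S{i}": "H010" for i in range(6)}
    m = matrix_from_strings(rows)
    filtered, report = apply_cascade(
        m, FilterParams(het_as_missing=True, snp_missing_max=0.2, maf_min=0.0)
    )
    assert filtered.variant_ids == ["snp2", "snp3", "snp4"]
    stage = next(s for s in report.stages if s.stage == "snp_missingness")
    assert stage.dropped_snps == ["snp1"]


def test_het_kept_when_not_recoded():
    rows = {f"S{i}": "H" for i in range(4)}
    m = matrix_from_strings(rows)
    filtered, _ = apply_cascade(
        m, FilterParams(het_as_missing=False, maf_min=0.0)
    )
    assert filtered.n_variants == 1


def test_order_sensitivity_of_sample_vs_maf_stage():
    """Removing a high-missing sample first flips a SNP across the MAF bound.

    The only ALT carrier at snp1 is a sample that itself fails the
    missingness filter; the cascade order (samples before MAF) therefore
    drops snp1, while the swapped order would keep it.
    """
    rows = {f"S{i}": "0" + ("1010" if i % 2 else "0101") for i in range(9)}
    rows["S9"] = "1...."  # sole ALT at snp1; 80% missing overall
    m = matrix_from_strings(rows)
    params = FilterParams(
        het_as_missing=False, snp_missing_max=0.5, sample_missing_max=0.5,
        maf_min=0.05,
    )
    filtered, report = apply_cascade(m, params)
    assert "snp1" not in filtered.variant_ids  # MAF 0 after S9 removed
    # swapped-order oracle: MAF over all 10 samples is 0.1 >= 0.05 -> kept
    maf_before_removal = minor_allele_frequency(m.calls[:, 0])
    assert maf_before_removal >= params.maf_min


def test_every_drop_attributed_to_exactly_one_stage():
    rows = {
        "S1": "0101010101",
        "S2": "010.010101",
        "S3": "1.........",
        "S4": "1111111111",
        "S5": "0101010101",
    }
    m = matrix_from_strings(rows)
    filtered, report = apply_cascade(
        m, FilterParams(snp_missing_max=0.25, sample_missing_max=0.5, maf_min=0.05)
    )
    dropped_snps = [s for rec in report.stages for s in rec.dropped_snps]
    dropped_samples = [s for rec in report.stages for s in rec.dropped_samples]
    assert len(dropped_snps) == len(set(dropped_snps))
    assert len(dropped_samples) == len(set(dropped_samples))
    assert set(dropped_snps) | set(filtered.variant_ids) == set(m.variant_ids)
    assert set(dropped_samples) | set(filtered.samples) == set(m.samples)
    last = report.stages[-1]
    assert (last.snps_after, last.samples_after) == (
        filtered.n_variants, filtered.n_samples
    )


def test_cascade_empty_result_names_stage():
    m = matrix_from_strings({"S1": "..", "S2": "00"})
    with pytest.raises(EmptyResultError) as err:
        apply_cascade(m, FilterParams(snp_missing_max=0.2, maf_min=0.0))
    assert err.value.stage == "snp_missingness"


@st.composite
def complete_call_matrices(draw):
    n_samples = draw(st.integers(3, 8))
    n_snps = draw(st.integers(2, 6))
    rows = {
        f"S{i}": "".join(
            draw(st.sampled_from("01")) for _ in range(n_snps)
        )
        for i in range(n_samples)
    }
    return matrix_from_strings(rows)


@given(complete_call_matrices())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_cascade_is_idempotent_on_complete_calls(m):
    """Without missing data the cascade reduces to the MAF stage, and a
    second application changes nothing."""
    params = FilterParams(snp_missing_max=0.4, sample_missing_max=0.5, maf_min=0.1)
    try:
        once, _ = apply_cascade(m, params)
    except EmptyResultError:
        return
    twice, _ = apply_cascade(once, params)
    assert twice.samples == once.samples
    assert twice.variants == once.variants
    assert np.array_equal(twice.calls, once.calls)


def test_cascade_idempotent_on_realistic_panels():
    """At realistic missingness (well inside the thresholds), one pass is a
    fixed point."""
    from haplopanel.synthetic_data import generate_panel, grain_length_preset

    params = FilterParams.preset("3krgp")
    for seed in range(3):
        panel = generate_panel(grain_length_preset(n_samples=500, seed=seed))
        for m in panel.matrices.values():
            once, _ = apply_cascade(m, params)
            twice, _ = apply_cascade(once, params)
            assert twice.samples == once.samples
            assert twice.variants == once.variants
            assert np.array_equal(twice.calls, once.calls)


def test_cascade_second_pass_can_tighten_at_the_boundary():
    """Documented edge case: the one-pass cascade is not a universal fixed
    point. When the MAF stage removes a SNP, a sample that sat exactly on
    the missingness boundary can exceed it on a second pass (its
    denominator shrank). The cascade is defined as a single pass."""
    m = matrix_from_strings({"S0": "00", "S1": "01", "S2": "0."})
    params = FilterParams(snp_missing_max=0.4, sample_missing_max=0.5, maf_min=0.1)
    once, _ = apply_cascade(m, params)
    assert once.variant_ids == ["snp2"]  # snp1 monomorphic, dropped by MAF
    assert once.samples == ["S0", "S1", "S2"]  # S2 at 1/2 = boundary, kept
    twice, _ = apply_cascade(once, params)
    assert twice.samples == ["S0", "S1"]  # S2 now 1/1 missing over snp2 alone


def test_param_validation():
    with pytest.raises(ValueError):
        FilterParams(maf_min=0.7)
    with pytest.raises(ValueError):
        FilterParams(snp_missing_max=1.5)
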