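"""Haplotype grouping: exact partition, rare rule, partial-match assignment,
coverage arithmetic, composition rollups, and survey mode."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplopanel.core import SampleMeta
from haplopanel.errors import ConfigurationError, HaplopanelError
from haplopanel.haplotyping import (
    NOVEL,
    RARE,
    UNCLASSIFIED,
    RareRule,
    characterize,
    composition_summary,
    coverage_percent,
    survey_panel,
)

from conftest import matrix_from_strings


def test_basic_grouping_with_rare():
    """Vectors {AAA x3, BBB x2, AAB x1} at min_count 2: Hap1(3), Hap2(2), 1 rare."""
    m = matrix_from_strings(
        {
            "S1": "000", "S2": "000", "S3": "000",
            "S4": "111", "S5": "111", "S6": "001",
        }
    )
    part = characterize(m, RareRule("min_count", 2))
    assert [(g.label, g.member_count) for g in part.groups] == [("Hap1", 3), ("Hap2", 2)]
    assert part.rare_samples == {"S6"}
    assert part.assignments["S6"] == RARE


def test_partial_match_unique_assigns():
    """A?A is compatible only with AAA among named groups -> Hap1."""
    m = matrix_from_strings(
        {
            "S1": "000", "S2": "000", "S3": "111", "S4": "111",
            "S5": "0.0",
        }
    )
    part = characterize(m, RareRule("min_count", 2))
    assert part.assignments["S5"] == "Hap1"
    assert part.group("Hap1").member_count == 3


def test_partial_match_ambiguous_unclassified():
    """?AB fits both AAB and BAB -> Unclassified."""
    m = matrix_from_strings(
        {
            "S1": "001", "S2": "001", "S3": "101", "S4": "101",
            "S5": ".01",
        }
    )
    part = characterize(m, RareRule("min_count", 2))
    assert part.assignments["S5"] == UNCLASSIFIED


def test_partial_compatible_only_with_rare_goes_rare():
    m = matrix_from_strings(
        {
            "S1": "000", "S2": "000", "S3": "111",
            "S4": "11.",
        }
    )
    part = characterize(m, RareRule("min_count", 2))
    # S3's vector is rare; S4 is compatible with it and with no named group
    assert part.assignments["S3"] == RARE
    assert part.assignments["S4"] == RARE


def test_partition_is_exact_on_toy():
    m = matrix_from_strings(
        {"S1": "00", "S2": "00", "S3": "11", "S4": "1.", "S5": "..", "S6": "01"}
    )
    part = characterize(m, RareRule("min_count", 2))
    part.validate()
    named = sum(g.member_count for g in part.groups)
    assert named + len(part.rare_samples) + len(part.unclassified_samples) == 6


def test_empty_matrix_rejected():
    m = matrix_from_strings({"S1": "00"})
    with pytest.raises(HaplopanelError):
        characterize(m.take_samples([]), RareRule("min_count", 1))


@st.composite
def random_matrices(draw):
    n_samples = draw(st.integers(4, 12))
    n_snps = draw(st.integers(2, 5))
    rows = {
        f"S{i}": "".join(draw(st.sampled_from("011.")) for _ in range(n_snps))
        for i in range(n_samples)
    }
    return matrix_from_strings(rows)


@given(random_matrices(), st.integers(1, 4))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_partition_property_random(m, threshold):
    """groups + rare + unclassified always partition the sample set exactly."""
    part = characterize(m, RareRule("min_count", threshold))
    part.validate()
    assert set(part.assignments) == set(m.samples)


def test_label_stability_under_sample_permutation():
    rows = {
        "S1": "010", "S2": "010", "S3": "010",
        "S4": "101", "S5": "101", "S6": "000", "S7": "000",
    }
    m1 = matrix_from_strings(rows)
    m2 = matrix_from_strings(dict(reversed(list(rows.items()))))
    p1 = characterize(m1, RareRule("min_count", 2))
    p2 = characterize(m2, RareRule("min_count", 2))
    assert {s: p1.assignments[s] for s in rows} == {s: p2.assignments[s] for s in rows}


def test_min_frequency_rule():
    rows = {f"S{i}": "00" for i in range(19)}
    rows["S19"] = "11"
    m = matrix_from_strings(rows)
    part = characterize(m, RareRule("min_frequency", 0.05))
    assert len(part.groups) == 2  # 1/20 = 0.05 meets the inclusive bound
    part = characterize(m, RareRule("min_frequency", 0.06))
    assert len(part.groups) == 1


@pytest.mark.parametrize(
    "classified, total, expected",
    [(2222, 2426, 92), (2873, 2993, 96), (0, 10, 0), (1, 200, 1), (1, 201, 0)],
)
def test_coverage_percent_rounds_half_up(classified, total, expected):
    assert coverage_percent(classified, total) == expected


def test_coverage_percent_rejects_bad_inputs():
    with pytest.raises(ValueError):
        coverage_percent(1, 0)
    with pytest.raises(ValueError):
        coverage_percent(5, 4)


def test_composition_varietal_rollup():
    """2 indica + 1 aus + 1 tropical-japonica -> Indica 75%, Japonica 25%."""
    m = matrix_from_strings({f"S{i}": "00" for i in range(4)})
    part = characterize(m, RareRule("min_count", 1))
    meta = [
        SampleMeta("S0", "indica"),
        SampleMeta("S1", "indica"),
        SampleMeta("S2", "aus"),
        SampleMeta("S3", "tropical-japonica"),
    ]
    df = composition_summary(part, meta)
    vg = df[(df["group"] == "Hap1") & (df["kind"] == "varietal_group")]
    pct = dict(zip(vg["category"], vg["percent"]))
    assert pct == {"Indica": 75.0, "Japonica": 25.0}


def test_composition_unknown_meta_and_percent_sum():
    m = matrix_from_strings({f"S{i}": "00" for i in range(3)})
    part = characterize(m, RareRule("min_count", 1))
    df = composition_summary(part, [])
    sub = df[(df["group"] == "Hap1") & (df["kind"] == "subpopulation")]
    assert sub["category"].tolist() == ["unknown"]
    assert sub["percent"].sum() == pytest.approx(100.0)
    for kind in ("subpopulation", "varietal_group", "grain_class"):
        total = df[(df["group"] == "Hap1") & (df["kind"] == kind)]["percent"].sum()
        assert total == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# survey mode
# ---------------------------------------------------------------------------

def _reference_groups():
    ref = matrix_from_strings(
        {
            "R1": "000", "R2": "000", "R3": "000",
            "R4": "011", "R5": "011",
            "R6": "110", "R7": "110",
        }
    )
    return characterize(ref, RareRule("min_count", 2))


def test_survey_counts_matching_samples():
    reference = _reference_groups()
    panel = matrix_from_strings({f"P{i}": "011" for i in range(5)})
    part = survey_panel(panel, reference.groups, reference.variants)
    assert part.group("Hap2").member_count == 5


def test_survey_het_or_missing_unclassified():
    reference = _reference_groups()
    panel = matrix_from_strings({"P1": "0H1", "P2": "0.1", "P3": "011"})
    part = survey_panel(panel, reference.groups, reference.variants)
    assert part.assignments["P1"] == UNCLASSIFIED
    assert part.assignments["P2"] == UNCLASSIFIED
    assert part.assignments["P3"] == "Hap2"


def test_survey_novel_vector_reported_not_invented():
    reference = _reference_groups()
    panel = matrix_from_strings({"P1": "101"})
    part = survey_panel(panel, reference.groups, reference.variants)
    assert part.assignments["P1"] == NOVEL
    assert list(part.novel_samples) == ["P1"]
    assert all(g.member_count == 0 for g in part.groups)


def test_survey_rejects_indistinguishable_reference_groups():
    reference = _reference_groups()
    # restrict panel to a SNP on which Hap1 and Hap2 collide
    panel = matrix_from_strings({"P1": "0"})
    with pytest.raises(ConfigurationError):
        survey_panel(panel.subset_variants(["snp1"]), reference.groups,
                     reference.variants)


def test_survey_consistent_with_full_characterization():
    """Complete-call samples get the same label via tag SNPs as via all SNPs."""
    from haplopanel.tagsnp import minimum_tag_set

    rows = {
        **{f"A{i}": "00110" for i in range(3)},
        **{f"B{i}": "01010" for i in range(3)},
        **{f"C{i}": "11001" for i in range(2)},
    }
    m = matrix_from_strings(rows)
    part = characterize(m, RareRule("min_count", 2))
    tags = minimum_tag_set(part.groups, part.variants, mode="exact")
    panel = m.subset_variants(tags.snp_ids)
    surveyed = survey_panel(panel, part.groups, part.variants)
    for sample in m.samples:
        assert surveyed.assignments[sample] == part.assignments[sample]
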