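"""One-way ANOVA / PVE, significance letters, two-locus classes, gene action."""

import numpy as np
import pandas as pd
import pytest

from haplopanel.association import (
    anova_pve,
    classify_two_locus,
    gene_action_report,
)
from haplopanel.errors import HaplopanelError
from haplopanel.synthetic_data import generate_cross_population, grain_length_preset

from conftest import matrix_from_strings


def pheno_from(values: dict[str, float], trait: str = "grain_length") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(values),
            "trait": trait,
            "environment": "Y1",
            "value": list(values.values()),
        }
    )


def test_pve_100_with_zero_within_variance():
    pheno = pheno_from({"a1": 7, "a2": 7, "b1": 5, "b2": 5})
    classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    res = anova_pve(pheno, classes)
    assert res.pve == pytest.approx(100.0)
    assert res.p_value == 0.0
    letters = dict(zip(res.table["class"], res.table["letter"]))
    assert set(letters["A"]) & set(letters["B"]) == set()


def test_pve_zero_when_labels_carry_no_signal():
    """Identical value sets split over two labels explain nothing."""
    pheno = pheno_from({"a1": 6.0, "a2": 7.0, "b1": 6.0, "b2": 7.0})
    classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    res = anova_pve(pheno, classes)
    assert res.pve == pytest.approx(0.0, abs=1e-9)


def test_pve_zero_with_equal_class_means():
    """Classes {6,8} and {5,9} share mean 7: between-SS is exactly zero."""
    pheno = pheno_from({"a1": 6, "a2": 8, "b1": 5, "b2": 9})
    classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    res = anova_pve(pheno, classes)
    assert res.pve == pytest.approx(0.0, abs=1e-9)
    letters = dict(zip(res.table["class"], res.table["letter"]))
    assert set(letters["A"]) & set(letters["B"])  # share a letter


@pytest.mark.parametrize("shift, scale", [(3.0, 1.0), (0.0, 2.5), (-1.2, 0.4)])
def test_pve_invariant_to_shift_and_positive_rescale(shift, scale):
    rng = np.random.default_rng(7)
    values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(6, 0.5, 40))}
    classes = {f"s{i}": ("A" if i % 2 else "B") for i in range(40)}
    base = anova_pve(pheno_from(values), classes)
    moved = {k: v * scale + shift for k, v in values.items()}
    res = anova_pve(pheno_from(moved), classes)
    assert res.pve == pytest.approx(base.pve, abs=1e-9)


def test_multi_environment_records_averaged_per_sample():
    pheno = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s3", "s4"],
            "trait": "grain_length",
            "environment": ["2017", "2018", "2017", "2017", "2017"],
            "value": [7.0, 8.0, 7.5, 5.0, 5.0],
        }
    )
    classes = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    res = anova_pve(pheno, classes)
    a_row = res.table[res.table["class"] == "A"]
    assert a_row["mean"].iloc[0] == pytest.approx(7.5)  # s1 averaged to 7.5
    assert a_row["n"].iloc[0] == 2


def test_singleton_class_kept_in_means_excluded_from_letters():
    pheno = pheno_from({"a1": 7, "a2": 7.2, "b1": 5, "b2": 5.1, "c1": 6.0})
    classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
    res = anova_pve(pheno, classes)
    c_row = res.table[res.table["class"] == "C"]
    assert len(c_row) == 1 and c_row["n"].iloc[0] == 1
    assert c_row["letter"].iloc[0] == ""
    assert res.excluded_from_letters == ["C"]


def test_fewer_than_two_usable_classes_rejected():
    pheno = pheno_from({"a1": 7, "a2": 7.1, "c1": 6.0})
    with pytest.raises(HaplopanelError):
        anova_pve(pheno, {"a1": "A", "a2": "A", "c1": "C"})
    with pytest.raises(HaplopanelError):
        anova_pve(pheno, {"a1": "A", "a2": "A"})


def test_letters_three_separated_groups():
    rng = np.random.default_rng(1)
    values, classes = {}, {}
    for label, mu in (("A", 7.5), ("B", 6.5), ("C", 5.5)):
        for i in range(15):
            sid = f"{label}{i}"
            values[sid] = float(rng.normal(mu, 0.1))
            classes[sid] = label
    res = anova_pve(pheno_from(values), classes, alpha=0.001)
    letters = dict(zip(res.table["class"], res.table["letter"]))
    assert len({letters["A"], letters["B"], letters["C"]}) == 3
    # table sorted by descending mean, longest class first
    assert res.table["class"].tolist() == ["A", "B", "C"]


# ---------------------------------------------------------------------------
# two-locus classification
# ---------------------------------------------------------------------------

def _two_snp_matrix(rows: dict[str, str]):
    """Two SNPs; long allele is ALT at snp1 and REF at snp2."""
    return matrix_from_strings(rows)


def test_four_class_labels_and_het_drop():
    m = _two_snp_matrix(
        {
            "LL": "10",  # long at both (ALT at snp1=long, REF at snp2=long)
            "LM": "11",
            "ML": "00",
            "MM": "01",
            "HX": "H0",
            "XN": "1.",
        }
    )
    long_allele = {"snp1": m.variants[0].alt_allele, "snp2": m.variants[1].ref_allele}
    classes, dropped = classify_two_locus(
        m, "snp1", "snp2", long_allele, mode="four_class"
    )
    assert classes == {"LL": "Class1", "LM": "Class2", "ML": "Class3", "MM": "Class4"}
    assert dropped == {"missing": 1, "het": 1}


def test_nine_class_keeps_heterozygotes():
    m = _two_snp_matrix({"S1": "H1", "S2": "HH", "S3": "00"})
    long_allele = {"snp1": m.variants[0].alt_allele, "snp2": m.variants[1].ref_allele}
    classes, dropped = classify_two_locus(
        m, "snp1", "snp2", long_allele, mode="nine_class"
    )
    assert classes["S1"] == "A-het/B-homo-M"
    assert classes["S2"] == "A-het/B-het"
    assert classes["S3"] == "A-homo-M/B-homo-L"
    assert dropped == {"missing": 0, "het": 0}


def test_unknown_long_allele_rejected():
    m = _two_snp_matrix({"S1": "00"})
    with pytest.raises(ValueError):
        classify_two_locus(m, "snp1", "snp2", {"snp1": "T", "snp2": "C"})


# ---------------------------------------------------------------------------
# gene action
# ---------------------------------------------------------------------------

def _cross(dominance_a: str, seed: int = 5, n: int = 900):
    region_a, region_b = grain_length_preset().regions
    matrix, pheno, _ = generate_cross_population(
        region_a, region_b, n=n, dominance_a=dominance_a, seed=seed
    )
    classes, _ = classify_two_locus(
        matrix, "GS3-SNP1", "qGL7.1-SNP1",
        {"GS3-SNP1": "A", "qGL7.1-SNP1": "G"},
        mode="nine_class",
    )
    return pheno, classes


def test_gene_action_detects_recessive_long_allele():
    """When long is recessive at A, het equals homo-M and homo-L exceeds het."""
    pheno, classes = _cross("recessive-long")
    report = gene_action_report(pheno, classes, alpha=0.001)
    a_rows = report[(report["locus"] == "A") & report["estimable"]]
    het_vs_m = a_rows[a_rows["contrast"] == "het_vs_homo-M"]
    l_vs_het = a_rows[a_rows["contrast"] == "homo-L_vs_het"]
    assert not het_vs_m["significant"].any()
    assert l_vs_het["significant"].all()
    assert report.attrs["verdicts"]["A"] == "recessive-long-like"


def test_gene_action_detects_additive_allele():
    pheno, classes = _cross("additive")
    report = gene_action_report(pheno, classes, alpha=0.001)
    a_rows = report[(report["locus"] == "A") & report["estimable"]]
    assert a_rows["significant"].all()
    assert report.attrs["verdicts"]["A"] == "additive-like"


def test_gene_action_empty_class_not_estimable():
    pheno, classes = _cross("recessive-long", n=200)
    # remove every A-het line within B homo-L to empty that contrast
    classes = {
        s: c for s, c in classes.items() if c != "A-het/B-homo-L"
    }
    report = gene_action_report(pheno, classes, alpha=0.001)
    gone = report[
        (report["locus"] == "A")
        & (report["fixed_other_state"] == "homo-L")
        & (report["contrast"] == "het_vs_homo-M")
    ]
    assert not gone["estimable"].iloc[0]
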