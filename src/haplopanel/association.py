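"""Haplotype/SNP-phenotype association and two-locus interaction analysis.

The central statistic is the one-way fixed-effects ANOVA of a phenotype
against a categorical classification (haplotype group, SNP allele class, or
two-locus genotype class), with percent variance explained

    PVE = 100 * SS_between / SS_total,

i.e. the R-squared of the one-way classification. Per-class significance
letters come from Tukey HSD all-pairs comparisons at a stated alpha,
rendered as a compact letter display (classes sharing no letter differ
significantly).

Two two-locus schemes are supported: the four-class scheme over homozygous
states only (Class1 = long/long ... Class4 = medium/medium, heterozygotes
dropped) used for inbred-line populations, and the nine-class scheme over
all 3x3 allele configurations used for segregating populations, from which
the gene-action contrasts (is the long allele recessive?) are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ALT, HET, MISSING, VariantMatrix
from .errors import HaplopanelError

logger = logging.getLogger(__name__)

HOMO_L = "homo-L"
HOMO_M = "homo-M"
HET_STATE = "het"

FOUR_CLASS_LABELS = {
    (HOMO_L, HOMO_L): "Class1",
    (HOMO_L, HOMO_M): "Class2",
    (HOMO_M, HOMO_L): "Class3",
    (HOMO_M, HOMO_M): "Class4",
}


@dataclass
class AssociationResult:
    """One-way classification of a phenotype."""

    classification: str
    table: pd.DataFrame  # class, n, mean, sd, letter
    f_stat: float
    p_value: float
    pve: float
    alpha: float
    correction: str = "tukey-hsd"
    excluded_from_letters: list[str] = field(default_factory=list)

    def class_mean(self, label: str) -> float:
        row = self.table[self.table["class"] == label]
        if row.empty:
            raise KeyError(f"no class {label!r} in association table")
        return float(row["mean"].iloc[0])


def _compact_letter_display(labels: list[str], means: dict[str, float],
                            significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds unordered label pairs that differ at alpha. The
    result assigns each label a string of letters such that two labels share
    a letter iff they are not declared significantly different.
    """
    ordered = sorted(labels, key=lambda l: (-means[l], l))
    sets: list[set[str]] = [set(ordered)]
    for a, b in sorted(significant):
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                for drop in (a, b):
                    reduced = s - {drop}
                    if not any(reduced <= other for other in sets):
                        sets.append(reduced)
    # deterministic letter order: by the best (longest-mean) member
    sets.sort(key=lambda s: min(ordered.index(l) for l in s) if s else len(ordered))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {l: "" for l in labels}
    for k, s in enumerate(sets):
        for l in ordered:
            if l in s:
                letters[l] += alphabet[k % len(alphabet)]
    return letters


def _mean_per_sample(pheno: pd.DataFrame, trait: str) -> pd.Series:
    sub = pheno[pheno["trait"] == trait]
    return sub.groupby("sample_id")["value"].mean()


def anova_pve(
    pheno: pd.DataFrame,
    classes: dict[str, str],
    trait: str = "grain_length",
    alpha: float = 0.05,
    classification: str = "haplotype",
) -> AssociationResult:
    """One-way ANOVA of a phenotype against a sample classification.

    Samples with multiple environment records are averaged per sample first
    (the line, not the plot, is the experimental unit). Classes with a
    single phenotyped sample contribute to the class-mean table but are
    excluded from the letters, with a warning.

    Raises
    ------
    HaplopanelError
        If fewer than two classes have at least two phenotyped samples.
    """
    per_sample = _mean_per_sample(pheno, trait)
    records = [
        (sample, label, per_sample[sample])
        for sample, label in classes.items()
        if sample in per_sample.index
    ]
    if not records:
        raise HaplopanelError("no phenotyped samples fall in any class")
    df = pd.DataFrame(records, columns=["sample_id", "class", "value"])
    sizes = df.groupby("class").size()
    if len(sizes) < 2:
        raise HaplopanelError("need at least two classes for ANOVA")
    usable = sizes[sizes >= 2].index.tolist()
    if len(usable) < 2:
        raise HaplopanelError("need at least two classes with >= 2 phenotyped samples")
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        logger.warning(
            "class(es) %s have a single phenotyped sample; excluded from letters",
            singletons,
        )

    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    sst = float(np.sum((y - grand) ** 2))
    group_stats = df.groupby("class")["value"].agg(["size", "mean", "std"])
    ssb = float(
        sum(r["size"] * (r["mean"] - grand) ** 2 for _, r in group_stats.iterrows())
    )
    ssw = max(sst - ssb, 0.0)
    k = len(group_stats)
    n = len(df)
    df_b, df_w = k - 1, n - k
    if sst == 0.0:
        f_stat, p_value, pve = 0.0, 1.0, 0.0
    elif ssw == 0.0 or df_w == 0:
        f_stat, p_value, pve = float("inf"), 0.0, 100.0 * ssb / sst
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p_value = float(stats.f.sf(f_stat, df_b, df_w))
        pve = 100.0 * ssb / sst

    letters = _letters_from_tukey(df[df["class"].isin(usable)], alpha)
    table = group_stats.reset_index().rename(columns={"size": "n"})
    table["sd"] = table["std"].fillna(0.0)
    table = table.drop(columns=["std"])
    table["letter"] = [letters.get(c, "") for c in table["class"]]
    table = table.sort_values("mean", ascending=False).reset_index(drop=True)
    return AssociationResult(
        classification=classification,
        table=table[["class", "n", "mean", "sd", "letter"]],
        f_stat=f_stat,
        p_value=p_value,
        pve=pve,
        alpha=alpha,
        excluded_from_letters=singletons,
    )


def _letters_from_tukey(df: pd.DataFrame, alpha: float) -> dict[str, str]:
    labels = sorted(df["class"].unique())
    means = df.groupby("class")["value"].mean().to_dict()
    if len(labels) < 2:
        return {l: "a" for l in labels}
    within = df.groupby("class")["value"].transform("mean")
    ssw = float(np.sum((df["value"] - within) ** 2))
    significant: set[tuple[str, str]] = set()
    if ssw == 0.0:
        # degenerate: identical within-class values; any mean difference is real
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if means[a] != means[b]:
                    significant.add(tuple(sorted((a, b))))
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(
            df["value"].to_numpy(), df["class"].to_numpy(), alpha=alpha
        )
        iu = zip(*np.triu_indices(len(res.groupsunique), 1))
        for (i, j), reject in zip(iu, res.reject):
            if reject:
                a, b = str(res.groupsunique[i]), str(res.groupsunique[j])
                significant.add(tuple(sorted((a, b))))
    return _compact_letter_display(labels, means, significant)


def _locus_state(call: int, long_is_alt: bool) -> str | None:
    if call == MISSING:
        return None
    if call == HET:
        return HET_STATE
    if (call == ALT) == long_is_alt:
        return HOMO_L
    return HOMO_M


def classify_two_locus(
    matrix: VariantMatrix,
    snp_a: str,
    snp_b: str,
    long_allele: dict[str, str],
    mode: str = "four_class",
    locus_names: tuple[str, str] = ("A", "B"),
) -> tuple[dict[str, str], dict[str, int]]:
    """Group samples by their allele configuration at two trait SNPs.

    Parameters
    ----------
    matrix : VariantMatrix
        Genotypes including the two SNPs (heterozygous calls permitted).
    snp_a, snp_b : str
        Variant ids of the locus-A and locus-B trait SNPs.
    long_allele : dict
        Base conferring the long-grain class at each SNP, e.g.
        ``{"GS3-SNP1": "A", "qGL7.1-SNP1": "G"}``.
    mode : {"four_class", "nine_class"}
        Four-class mode keeps homozygous samples only (Class1=L/L,
        Class2=L/M, Class3=M/L, Class4=M/M) and drops heterozygotes with a
        logged count; nine-class mode enumerates all 3x3 states with labels
        like ``"A-het/B-homo-M"``.

    Returns
    -------
    (classes, dropped)
        ``classes`` maps sample id to class label; ``dropped`` counts
        samples excluded for missing calls or (in four-class mode)
        heterozygosity.
    """
    if mode not in ("four_class", "nine_class"):
        raise ValueError(f"unknown two-locus mode {mode!r}")
    ja = matrix.variant_index(snp_a)
    jb = matrix.variant_index(snp_b)
    va, vb = matrix.variants[ja], matrix.variants[jb]
    orientation = {}
    for v, snp in ((va, snp_a), (vb, snp_b)):
        base = long_allele[snp].upper()
        if base == v.alt_allele:
            orientation[snp] = True
        elif base == v.ref_allele:
            orientation[snp] = False
        else:
            raise ValueError(
                f"long allele {base!r} for {snp} matches neither ref "
                f"{v.ref_allele!r} nor alt {v.alt_allele!r}"
            )
    name_a, name_b = locus_names
    classes: dict[str, str] = {}
    dropped = {"missing": 0, "het": 0}
    for i, sample in enumerate(matrix.samples):
        state_a = _locus_state(int(matrix.calls[i, ja]), orientation[snp_a])
        state_b = _locus_state(int(matrix.calls[i, jb]), orientation[snp_b])
        if state_a is None or state_b is None:
            dropped["missing"] += 1
            continue
        if mode == "four_class":
            if HET_STATE in (state_a, state_b):
                dropped["het"] += 1
                continue
            classes[sample] = FOUR_CLASS_LABELS[(state_a, state_b)]
        else:
            classes[sample] = f"{name_a}-{state_a}/{name_b}-{state_b}"
    if dropped["het"]:
        logger.info("four-class mode dropped %d heterozygous sample(s)", dropped["het"])
    return classes, dropped


def nine_class_label(state_a: str, state_b: str,
                     locus_names: tuple[str, str] = ("A", "B")) -> str:
    return f"{locus_names[0]}-{state_a}/{locus_names[1]}-{state_b}"


def gene_action_report(
    pheno: pd.DataFrame,
    classes: dict[str, str],
    trait: str = "grain_length",
    alpha: float = 0.05,
    locus_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Gene-action contrasts over a nine-class two-locus classification.

    For each locus, within every fixed state of the other locus, compares
    the heterozygous class against each homozygous class by a two-sample
    Welch t test: a recessive long allele shows het ~ homo-M together with
    homo-L > het. Contrasts whose operand classes are empty or singleton are
    marked not estimable. The summary row per locus reads
    "recessive-long-like", "additive-like", or "insufficient evidence".
    """
    per_sample = _mean_per_sample(pheno, trait)
    values: dict[str, list[float]] = {}
    for sample, label in classes.items():
        if sample in per_sample.index:
            values.setdefault(label, []).append(float(per_sample[sample]))

    name_a, name_b = locus_names
    states = (HOMO_L, HET_STATE, HOMO_M)

    def label_of(locus, state, other_state):
        if locus == name_a:
            return nine_class_label(state, other_state, locus_names)
        return nine_class_label(other_state, state, locus_names)

    rows = []
    verdict_votes: dict[str, dict[str, int]] = {
        name_a: {"het_vs_M_sig": 0, "het_vs_M_ns": 0, "L_vs_het_sig": 0, "L_vs_het_ns": 0},
        name_b: {"het_vs_M_sig": 0, "het_vs_M_ns": 0, "L_vs_het_sig": 0, "L_vs_het_ns": 0},
    }
    for locus in (name_a, name_b):
        for fixed in states:
            for contrast, (s1, s2) in (
                ("het_vs_homo-M", (HET_STATE, HOMO_M)),
                ("homo-L_vs_het", (HOMO_L, HET_STATE)),
            ):
                g1 = values.get(label_of(locus, s1, fixed), [])
                g2 = values.get(label_of(locus, s2, fixed), [])
                if len(g1) < 2 or len(g2) < 2:
                    rows.append(
                        {
                            "locus": locus,
                            "fixed_other_state": fixed,
                            "contrast": contrast,
                            "n1": len(g1),
                            "n2": len(g2),
                            "mean_diff": np.nan,
                            "p_value": np.nan,
                            "significant": False,
                            "estimable": False,
                        }
                    )
                    continue
                diff = float(np.mean(g1) - np.mean(g2))
                if np.var(g1) == 0 and np.var(g2) == 0:
                    p = 0.0 if diff != 0 else 1.0
                else:
                    p = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
                sig = p < alpha
                rows.append(
                    {
                        "locus": locus,
                        "fixed_other_state": fixed,
                        "contrast": contrast,
                        "n1": len(g1),
                        "n2": len(g2),
                        "mean_diff": diff,
                        "p_value": p,
                        "significant": sig,
                        "estimable": True,
                    }
                )
                key = "het_vs_M" if contrast == "het_vs_homo-M" else "L_vs_het"
                verdict_votes[locus][f"{key}_{'sig' if sig else 'ns'}"] += 1

    report = pd.DataFrame(rows)
    verdicts = {}
    for locus, v in verdict_votes.items():
        if v["het_vs_M_sig"] == 0 and v["L_vs_het_sig"] == 0:
            verdicts[locus] = "insufficient evidence"
        elif v["het_vs_M_sig"] == 0 and v["L_vs_het_sig"] > 0:
            verdicts[locus] = "recessive-long-like"
        elif v["het_vs_M_sig"] > 0 and v["L_vs_het_sig"] > 0:
            verdicts[locus] = "additive-like"
        else:
            verdicts[locus] = "dominant-long-like"
    report.attrs["verdicts"] = verdicts
    return report
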