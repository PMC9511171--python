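"""Haplotype grouping, rare-haplotype handling, and panel surveys.

A haplotype is the combination of alleles across all retained SNPs of a
region; two samples share a haplotype iff their allele vectors are
identical. Samples with complete calls are grouped exactly; groups meeting
the rare rule are named ``Hap1, Hap2, ...`` in descending size. Samples
with missing calls are assigned to a named group only when their observed
calls are compatible with exactly one named group's vector; compatibility
with several groups, or with none, sends them to Unclassified, and
compatibility with only a rare vector sends them to Rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    ALT,
    HET,
    MISSING,
    REF,
    VARIETAL_GROUPS,
    SampleMeta,
    Variant,
    VariantMatrix,
)
from .errors import ConfigurationError, FormatError, HaplopanelError

RARE = "RARE"
UNCLASSIFIED = "UNCLASSIFIED"
NOVEL = "NOVEL"


@dataclass(frozen=True)
class RareRule:
    """Threshold below which a haplotype is considered rare.

    ``min_count`` mode names groups with at least ``threshold`` members
    (strictly fewer is rare); ``min_frequency`` mode names groups whose
    panel frequency is at least ``threshold``.
    """

    mode: str = "min_count"
    threshold: float = 30

    def __post_init__(self):
        if self.mode not in ("min_count", "min_frequency"):
            raise ValueError(f"unknown rare-rule mode {self.mode!r}")
        if self.mode == "min_count":
            if self.threshold < 1 or int(self.threshold) != self.threshold:
                raise ValueError("min_count threshold must be an integer >= 1")
        elif not 0.0 < self.threshold < 1.0:
            raise ValueError("min_frequency threshold must be in (0, 1)")

    def is_named(self, count: int, total: int) -> bool:
        if self.mode == "min_count":
            return count >= int(self.threshold)
        return total > 0 and count / total >= self.threshold


@dataclass
class HaplotypeGroup:
    """A named haplotype: an allele vector plus its membership."""

    label: str
    alleles: np.ndarray  # REF/ALT codes over the region's retained SNPs
    member_count: int = 0
    composition: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if np.any((self.alleles != REF) & (self.alleles != ALT)):
            raise FormatError(f"group {self.label}: allele vector must be REF/ALT only")


@dataclass
class HaplotypePartition:
    """Full assignment of a panel's samples to haplotype groups.

    Named groups, the rare set, the unclassified set and (in survey mode)
    the novel set partition the sample set exactly.
    """

    variants: list[Variant]
    groups: list[HaplotypeGroup]
    rare_samples: set[str] = field(default_factory=set)
    unclassified_samples: set[str] = field(default_factory=set)
    novel_samples: dict[str, tuple] = field(default_factory=dict)
    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.assignments)

    @property
    def n_classified(self) -> int:
        return sum(g.member_count for g in self.groups)

    def group(self, label: str) -> HaplotypeGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"no haplotype group labelled {label!r}")

    def validate(self) -> None:
        """Check the exact-partition invariant."""
        named = {s for s, lab in self.assignments.items()
                 if lab not in (RARE, UNCLASSIFIED, NOVEL)}
        pools = [named, self.rare_samples, self.unclassified_samples,
                 set(self.novel_samples)]
        union: set[str] = set()
        total = 0
        for pool in pools:
            union |= pool
            total += len(pool)
        if total != len(union) or union != set(self.assignments):
            raise HaplopanelError("haplotype partition is not exact")
        if sum(g.member_count for g in self.groups) != len(named):
            raise HaplopanelError("group member counts disagree with assignments")


def _sorted_named_vectors(
    vector_counts: dict[tuple, int], rule: RareRule, total: int
) -> tuple[list[tuple], list[tuple]]:
    """Split complete-call vectors into named and rare, named sorted for labeling."""
    named = [v for v, c in vector_counts.items() if rule.is_named(c, total)]
    rare = [v for v in vector_counts if v not in set(named)]
    named.sort(key=lambda v: (-vector_counts[v], v))
    return named, rare


def characterize(matrix: VariantMatrix, rule: RareRule) -> HaplotypePartition:
    """Partition a filtered matrix into haplotype groups.

    Parameters
    ----------
    matrix : VariantMatrix
        Already filtered; calls must contain only REF/ALT/MISSING.
    rule : RareRule
        Threshold separating named groups from rare haplotypes. Frequency-mode
        thresholds use the full filtered sample count as denominator.

    Returns
    -------
    HaplotypePartition
        Named groups labelled Hap1..HapN in descending final member count
        (ties broken by lexicographic allele vector, REF before ALT).
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise HaplopanelError("cannot characterize an empty matrix")
    if np.any(matrix.calls == HET):
        raise FormatError(
            "heterozygous calls present; run the filtering cascade "
            "(het_as_missing) before haplotype characterization"
        )
    total = matrix.n_samples
    complete = ~np.any(matrix.calls == MISSING, axis=1)

    vector_counts: dict[tuple, int] = {}
    for i in np.flatnonzero(complete):
        vec = tuple(int(c) for c in matrix.calls[i, :])
        vector_counts[vec] = vector_counts.get(vec, 0) + 1

    named_vectors, rare_vectors = _sorted_named_vectors(vector_counts, rule, total)
    named_arr = np.array(named_vectors, dtype=np.int8) if named_vectors else None
    rare_arr = np.array(rare_vectors, dtype=np.int8) if rare_vectors else None
    vector_rank = {v: k for k, v in enumerate(named_vectors)}

    members: dict[int, list[str]] = {k: [] for k in range(len(named_vectors))}
    rare_samples: set[str] = set()
    unclassified: set[str] = set()

    for i, sample in enumerate(matrix.samples):
        row = matrix.calls[i, :]
        if complete[i]:
            vec = tuple(int(c) for c in row)
            if vec in vector_rank:
                members[vector_rank[vec]].append(sample)
            else:
                rare_samples.add(sample)
            continue
        observed = row != MISSING
        n_named = 0
        hit = -1
        if named_arr is not None and named_arr.size:
            compat = np.all(named_arr[:, observed] == row[observed], axis=1)
            n_named = int(compat.sum())
            if n_named == 1:
                hit = int(np.flatnonzero(compat)[0])
        if n_named == 1:
            members[hit].append(sample)
        elif n_named == 0:
            n_rare = 0
            if rare_arr is not None and rare_arr.size:
                n_rare = int(
                    np.all(rare_arr[:, observed] == row[observed], axis=1).sum()
                )
            if n_rare >= 1:
                rare_samples.add(sample)
            else:
                unclassified.add(sample)
        else:
            unclassified.add(sample)

    # Re-rank by final member count so Hap1 is the most common group even
    # after partial-match assignment; ties break on the allele vector.
    order = sorted(
        range(len(named_vectors)),
        key=lambda k: (-len(members[k]), named_vectors[k]),
    )
    groups: list[HaplotypeGroup] = []
    assignments: dict[str, str] = {}
    for rank, k in enumerate(order, start=1):
        label = f"Hap{rank}"
        groups.append(
            HaplotypeGroup(
                label=label,
                alleles=np.array(named_vectors[k], dtype=np.int8),
                member_count=len(members[k]),
            )
        )
        for sample in members[k]:
            assignments[sample] = label
    for sample in rare_samples:
        assignments[sample] = RARE
    for sample in unclassified:
        assignments[sample] = UNCLASSIFIED

    partition = HaplotypePartition(
        variants=list(matrix.variants),
        groups=groups,
        rare_samples=rare_samples,
        unclassified_samples=unclassified,
        assignments=assignments,
    )
    partition.validate()
    return partition


def survey_panel(
    panel: VariantMatrix, reference_groups: list[HaplotypeGroup],
    reference_variants: list[Variant] | None = None,
) -> HaplotypePartition:
    """Assign a survey panel's samples to reference haplotype groups.

    The panel is genotyped only at a tag-SNP subset. Reference group vectors
    are restricted to the panel's SNPs (matched by id when
    ``reference_variants`` is given; otherwise vectors must already align
    with the panel's variant order). Any heterozygous or missing call at a
    tag SNP makes a sample Unclassified. Complete vectors matching no
    reference group are reported as Novel with their vector — no new groups
    are invented.

    Raises
    ------
    ConfigurationError
        If two reference groups are indistinguishable on the panel's SNPs.
    """
    if reference_variants is not None:
        order = {v.id: j for j, v in enumerate(reference_variants)}
        missing_ids = [v.id for v in panel.variants if v.id not in order]
        if missing_ids:
            raise ConfigurationError(
                f"panel SNPs absent from the reference definition: {missing_ids}"
            )
        idx = [order[v.id] for v in panel.variants]
        restricted = [
            HaplotypeGroup(g.label, g.alleles[idx], g.member_count)
            for g in reference_groups
        ]
    else:
        restricted = [
            HaplotypeGroup(g.label, g.alleles, g.member_count)
            for g in reference_groups
        ]
        for g in restricted:
            if len(g.alleles) != panel.n_variants:
                raise ConfigurationError(
                    f"group {g.label}: vector length {len(g.alleles)} does not "
                    f"match the panel's {panel.n_variants} SNPs"
                )

    seen: dict[tuple, str] = {}
    for g in restricted:
        key = tuple(int(a) for a in g.alleles)
        if key in seen:
            raise ConfigurationError(
                f"reference groups {seen[key]} and {g.label} are "
                "indistinguishable on the provided SNPs"
            )
        seen[key] = g.label

    counts = {g.label: 0 for g in restricted}
    assignments: dict[str, str] = {}
    unclassified: set[str] = set()
    novel: dict[str, tuple] = {}
    for i, sample in enumerate(panel.samples):
        row = panel.calls[i, :]
        if np.any((row == HET) | (row == MISSING)):
            unclassified.add(sample)
            assignments[sample] = UNCLASSIFIED
            continue
        key = tuple(int(c) for c in row)
        label = seen.get(key)
        if label is None:
            novel[sample] = key
            assignments[sample] = NOVEL
        else:
            counts[label] += 1
            assignments[sample] = label

    groups = [
        HaplotypeGroup(g.label, g.alleles, counts[g.label]) for g in restricted
    ]
    partition = HaplotypePartition(
        variants=list(panel.variants),
        groups=groups,
        rare_samples=set(),
        unclassified_samples=unclassified,
        novel_samples=novel,
        assignments=assignments,
    )
    partition.validate()
    return partition


def coverage_percent(classified: int, total: int) -> int:
    """Percent of samples covered by the named groups, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= classified <= total:
        raise ValueError("classified must be between 0 and total")
    pct = Decimal(100 * classified) / Decimal(total)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def composition_summary(
    partition: HaplotypePartition, meta: Iterable[SampleMeta]
) -> pd.DataFrame:
    """Per-group composition by subpopulation, varietal group, and grain class.

    Returns a long-format table: one row per (group, category kind,
    category, count, percent-within-group). Samples absent from the
    metadata are counted as "unknown". Varietal groups roll subpopulations
    up into Indica / Japonica / Admix / Unknown.
    """
    lookup = {m.sample_id: m for m in meta}
    members: dict[str, list[str]] = {}
    for sample, label in partition.assignments.items():
        members.setdefault(label, []).append(sample)

    rows = []
    labels = [g.label for g in partition.groups] + [RARE, UNCLASSIFIED]
    if partition.novel_samples:
        labels.append(NOVEL)
    for label in labels:
        ids = members.get(label, [])
        n = len(ids)
        tallies: dict[tuple[str, str], int] = {}
        for sid in ids:
            m = lookup.get(sid)
            subpop = m.subpopulation if m else "unknown"
            grain = m.grain_class if m else "unknown"
            for kind, cat in (
                ("subpopulation", subpop),
                ("varietal_group", VARIETAL_GROUPS[subpop]),
                ("grain_class", grain),
            ):
                tallies[(kind, cat)] = tallies.get((kind, cat), 0) + 1
        for (kind, cat), count in sorted(tallies.items()):
            rows.append(
                {
                    "group": label,
                    "kind": kind,
                    "category": cat,
                    "n": count,
                    "percent": 100.0 * count / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["group", "kind", "category", "n", "percent"])
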