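"""Minimum discriminating SNP-set selection (tag SNPs) for haplotype groups.

A SNP *separates* a pair of groups when its alleles differ between them. A
SNP set is *discriminating* when every unordered pair of groups is
separated by at least one SNP in the set. The minimum set is found by an
exact increasing-cardinality search over SNP equivalence classes (SNPs that
induce the same bipartition of the groups are interchangeable), with a
greedy set-cover fallback for instances the exact search cannot cover.

Because every SNP is biallelic, any discriminating set must satisfy the
information bound ``size >= ceil(log2(n_groups))``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

from .core import Variant
from .haplotyping import HaplotypeGroup
from .errors import InseparableGroupsError

logger = logging.getLogger(__name__)

#: Cap on subsets examined by the exact search in auto mode before the
#: greedy fallback takes over.
AUTO_SUBSET_BUDGET = 2_000_000


@dataclass
class TagSet:
    """A SNP subset proven to discriminate all named haplotype groups."""

    snp_ids: list[str]
    method: str  # "exact" or "greedy"
    pair_coverage: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def _pairs(n: int):
    return itertools.combinations(range(n), 2)


def _check_groups(groups: list[HaplotypeGroup]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two haplotype groups to discriminate")
    bad = [
        (groups[i].label, groups[j].label)
        for i, j in _pairs(len(groups))
        if tuple(groups[i].alleles) == tuple(groups[j].alleles)
    ]
    if bad:
        raise InseparableGroupsError(bad)


def _snp_index(snp_id: str, variants: list[Variant]) -> int:
    for j, v in enumerate(variants):
        if v.id == snp_id:
            return j
    raise KeyError(f"unknown SNP id {snp_id!r}")


def is_discriminating(
    snp_ids, groups: list[HaplotypeGroup], variants: list[Variant]
) -> tuple[bool, list[tuple[str, str]]]:
    """Test whether a SNP set separates every pair of groups.

    Returns ``(ok, failing_pairs)`` where ``failing_pairs`` lists the group
    label pairs not separated by any SNP in the set.
    """
    if len(groups) < 2:
        raise ValueError("need at least two haplotype groups to discriminate")
    cols = [_snp_index(s, variants) for s in snp_ids]
    failing = []
    for i, j in _pairs(len(groups)):
        if all(groups[i].alleles[c] == groups[j].alleles[c] for c in cols):
            failing.append((groups[i].label, groups[j].label))
    return (len(failing) == 0, failing)


def distinguishing_power(
    snp_id: str, groups: list[HaplotypeGroup], variants: list[Variant]
) -> int:
    """Number of group pairs a single SNP separates.

    A SNP splitting the groups k / (n-k) separates k*(n-k) pairs.
    """
    c = _snp_index(snp_id, variants)
    n_alt = sum(1 for g in groups if g.alleles[c] != groups[0].alleles[c])
    return n_alt * (len(groups) - n_alt)


def _pair_masks(groups: list[HaplotypeGroup], variants: list[Variant]):
    """Per-SNP bitmask of separated pairs, plus the full-coverage mask."""
    n = len(groups)
    pair_bit = {p: 1 << k for k, p in enumerate(_pairs(n))}
    full = (1 << len(pair_bit)) - 1
    masks = []
    for c in range(len(variants)):
        m = 0
        for (i, j), bit in pair_bit.items():
            if groups[i].alleles[c] != groups[j].alleles[c]:
                m |= bit
        masks.append(m)
    return masks, full, pair_bit


def _equivalence_classes(masks, variants: list[Variant], priority: list[str] | None):
    """Collapse SNPs with identical separated-pair masks; pick a representative.

    The representative is the highest-priority SNP in the class, then the one
    at the lowest genomic position (then lexicographic id) — deterministic and
    assay-friendly.
    """
    prio = {s: k for k, s in enumerate(priority or [])}

    def sort_key(c):
        v = variants[c]
        return (prio.get(v.id, len(prio)), v.chrom, v.pos, v.id)

    classes: dict[int, list[int]] = {}
    for c, m in enumerate(masks):
        if m == 0:
            continue  # constant across groups: useless
        classes.setdefault(m, []).append(c)
    reps = [min(cols, key=sort_key) for cols in classes.values()]
    reps.sort(key=sort_key)
    return reps


def minimum_tag_set(
    groups: list[HaplotypeGroup],
    variants: list[Variant],
    mode: str = "auto",
    exact_size_limit: int = 10,
    priority: list[str] | None = None,
) -> TagSet:
    """Find a minimum (or near-minimum) discriminating SNP set.

    Parameters
    ----------
    groups, variants
        Named haplotype groups and the region's SNPs (vectors aligned with
        ``variants``). Groups must be pairwise distinct on the full SNP set.
    mode : {"exact", "greedy", "auto"}
        ``exact`` guarantees minimum cardinality via increasing-size subset
        search over SNP equivalence classes; ``greedy`` adds the SNP
        resolving the most outstanding pairs at each step; ``auto`` runs
        exact while the search stays within budget, else falls back to
        greedy with a logged bound statement.
    exact_size_limit : int
        Largest cardinality the exact search will attempt.
    priority : list of SNP ids, optional
        Preferred SNPs (e.g. known functional mutations), honored only among
        otherwise equivalent choices.

    Raises
    ------
    InseparableGroupsError
        If two groups share identical vectors on the full SNP set.
    """
    _check_groups(groups)
    if mode not in ("exact", "greedy", "auto"):
        raise ValueError(f"unknown tag-set mode {mode!r}")
    masks, full, pair_bit = _pair_masks(groups, variants)
    reps = _equivalence_classes(masks, variants, priority)
    union = 0
    for c in reps:
        union |= masks[c]
    if union != full:
        failing = [
            (groups[i].label, groups[j].label)
            for (i, j), bit in pair_bit.items()
            if not union & bit
        ]
        raise InseparableGroupsError(failing)

    chosen: list[int] | None = None
    method = mode
    if mode in ("exact", "auto"):
        budget = None if mode == "exact" else AUTO_SUBSET_BUDGET
        chosen = _exact_search(masks, full, reps, exact_size_limit, budget)
        if chosen is not None:
            method = "exact"
        elif mode == "exact":
            raise RuntimeError(
                f"exact search found no discriminating set of size <= {exact_size_limit}"
            )
    if chosen is None:
        if mode == "auto":
            logger.warning(
                "exact search exceeded its budget; greedy result is an upper "
                "bound on the minimum set size (lower bound %d)",
                math.ceil(math.log2(len(groups))),
            )
        chosen = _greedy_search(masks, full, reps)
        method = "greedy"

    chosen_sorted = sorted(chosen, key=lambda c: (variants[c].chrom, variants[c].pos))
    snp_ids = [variants[c].id for c in chosen_sorted]
    coverage = {
        (groups[i].label, groups[j].label): [
            variants[c].id for c in chosen_sorted if masks[c] & bit
        ]
        for (i, j), bit in pair_bit.items()
    }
    return TagSet(snp_ids=snp_ids, method=method, pair_coverage=coverage)


def _exact_search(masks, full, reps, size_limit, budget):
    lower = 1
    examined = 0
    for k in range(lower, min(size_limit, len(reps)) + 1):
        for combo in itertools.combinations(reps, k):
            examined += 1
            if budget is not None and examined > budget:
                return None
            acc = 0
            for c in combo:
                acc |= masks[c]
            if acc == full:
                return list(combo)
    return None


def _greedy_search(masks, full, reps):
    chosen: list[int] = []
    covered = 0
    remaining = list(reps)
    while covered != full:
        best = max(remaining, key=lambda c: bin(masks[c] & ~covered).count("1"))
        if masks[best] & ~covered == 0:
            raise InseparableGroupsError([("<unresolved>", "<unresolved>")])
        chosen.append(best)
        covered |= masks[best]
        remaining.remove(best)
    return chosen
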