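"""Subset-size accounting: totals, percentages, unique and overlap counts.

Percentages are expressed relative to the total number of hits *with
multiplicity* (a transcript that satisfies two subset rules contributes
two hits), which is how the study's summary shares are defined. Overlap
accounting (Venn regions) is restricted to the four SE-stage subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .config import ORGANOGENESIS_SUBSETS, RunConfig, SE_SUBSETS
from .deg import DegClassification


@dataclass(frozen=True)
class SubsetSummary:
    """Sizes, share percentages and SE unique-member counts."""

    sizes: dict[str, int]
    total_hits: int
    percentages: dict[str, float]
    organogenesis_total: int
    se_total: int
    unique_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "sizes": dict(self.sizes),
            "total_hits": self.total_hits,
            "percentages": dict(self.percentages),
            "organogenesis_total": self.organogenesis_total,
            "se_total": self.se_total,
            "unique_counts": dict(self.unique_counts),
        }


def _unique_counts(se_members: dict[str, frozenset[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for label, members in se_members.items():
        others: set[str] = set()
        for other, m in se_members.items():
            if other != label:
                others |= m
        counts[label] = len(members - others)
    return counts


def summarize(classification: DegClassification, config: RunConfig | None = None) -> SubsetSummary:
    """Compute sizes, totals, multiplicity percentages and SE unique counts.

    With an empty classification (total hits 0) percentages are empty
    rather than NaN.
    """
    cfg = config or RunConfig()
    if not classification.memberships:
        raise ValueError("classification has an empty subset vocabulary")
    sizes = {label: len(m) for label, m in classification.memberships.items()}
    total_hits = sum(sizes.values())
    if total_hits:
        percentages = {
            label: cfg.round(100.0 * size / total_hits) for label, size in sizes.items()
        }
    else:
        percentages = {}
    organogenesis_total = sum(sizes.get(s, 0) for s in ORGANOGENESIS_SUBSETS)
    se_total = sum(sizes.get(s, 0) for s in SE_SUBSETS)
    se_members = {s: classification.memberships[s] for s in SE_SUBSETS if s in classification.memberships}
    return SubsetSummary(
        sizes=sizes,
        total_hits=total_hits,
        percentages=percentages,
        organogenesis_total=organogenesis_total,
        se_total=se_total,
        unique_counts=_unique_counts(se_members),
    )


def summarize_sizes(
    sizes: dict[str, int], config: RunConfig | None = None
) -> SubsetSummary:
    """Summarize from printed subset sizes alone (no member identities).

    Used to reproduce report-level arithmetic when only the per-subset
    counts are available; unique counts are not derivable and are empty.
    """
    cfg = config or RunConfig()
    if not sizes:
        raise ValueError("no subset sizes given")
    total_hits = sum(sizes.values())
    percentages = (
        {label: cfg.round(100.0 * n / total_hits) for label, n in sizes.items()}
        if total_hits
        else {}
    )
    return SubsetSummary(
        sizes=dict(sizes),
        total_hits=total_hits,
        percentages=percentages,
        organogenesis_total=sum(sizes.get(s, 0) for s in ORGANOGENESIS_SUBSETS),
        se_total=sum(sizes.get(s, 0) for s in SE_SUBSETS),
        unique_counts={},
    )


def overlap_table(classification: DegClassification) -> dict[tuple[str, ...], int]:
    """Venn-region counts over the four SE subsets.

    Keys are the sorted tuples of subset labels a region belongs to exactly;
    only non-empty regions are reported. Region counts sum to the size of
    the SE union, each transcript landing in exactly one region.
    """
    se_members = classification.se_memberships()
    missing = [s for s in SE_SUBSETS if s not in classification.memberships]
    if missing:
        raise ValueError(f"classification lacks SE subset(s) {missing}")
    regions: dict[tuple[str, ...], int] = {}
    labels = list(SE_SUBSETS)
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(set(se_members[c]) for c in combo))
            outside: set[str] = set()
            for label in labels:
                if label not in combo:
                    outside |= se_members[label]
            count = len(inside - outside)
            if count:
                regions[tuple(combo)] = count
    return regions
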