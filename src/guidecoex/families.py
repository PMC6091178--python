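"""Family-abundance ranking of co-expressed TFs and the cross-guide Venn step.

After the |r| screen, each guide has a set of strongly co-expressed genes.
Those present in the TF-family annotation are tallied per family; the
top-K most abundant families per guide (K = 5 by default) are then
intersected across guides. A family that tops every guide's list - as the
G2-like family does for the photoperiodic flowering guides - is the
prioritized candidate family. Ranking is by raw member count, not by a
statistical enrichment test.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import pandas as pd

from guidecoex.correlation import ThresholdSpec
from guidecoex.io import TFFamilyAnnotation

__all__ = [
    "FamilyRanking",
    "SharedFamilyResult",
    "rank_families",
    "shared_top_families",
]

logger = logging.getLogger("guidecoex")


@dataclass
class FamilyRanking:
    """Per-guide ordered (family, member_count) list.

    Ordered by count descending, ties broken lexicographically by family
    name, truncated to at most top_k entries. ``total_annotated`` is the
    number of annotated genes that passed the screen (the full-list counts
    sum to it); ``n_unannotated`` counts screened genes absent from the
    annotation, which are ignored.
    """

    guide_id: str
    ranked: list[tuple[str, int]]
    threshold_used: Optional[ThresholdSpec] = None
    total_annotated: int = 0
    n_unannotated: int = 0

    @property
    def top_families(self) -> frozenset[str]:
        return frozenset(f for f, _ in self.ranked)


@dataclass
class SharedFamilyResult:
    """Intersection of per-guide top-K family sets plus Venn region counts.

    ``venn_counts`` maps every nonempty subset of guides (as a frozenset of
    guide ids) to the number of families found in exactly those guides'
    top-K sets; the region counts partition the union of the top-K sets.
    """

    per_guide_top: dict[str, frozenset[str]]
    intersection: frozenset[str]
    venn_counts: dict[frozenset[str], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Venn regions as a TSV-ready table, deterministically ordered."""
        guides = sorted(self.per_guide_top)
        rows = []
        for region, count in sorted(
            self.venn_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            rows.append(
                {
                    "region": "&".join(sorted(region, key=guides.index)),
                    "n_guides": len(region),
                    "n_families": count,
                }
            )
        return pd.DataFrame.from_records(rows, columns=["region", "n_guides", "n_families"])


def rank_families(
    coexpressed: set[str],
    annotation: TFFamilyAnnotation,
    top_k: int = 5,
    guide_id: str = "",
    threshold: Optional[ThresholdSpec] = None,
) -> FamilyRanking:
    """Rank TF families by abundance among a guide's co-expressed genes.

    Genes absent from the annotation are ignored (counted in the log).
    Ties at the top_k boundary are resolved by keeping the
    lexicographically first families, so the result is deterministic;
    a truncated tie is logged.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    annotated = [g for g in coexpressed if g in annotation]
    n_unannotated = len(coexpressed) - len(annotated)
    if n_unannotated:
        logger.info(
            "guide %s: %d co-expressed gene(s) not in the family annotation, ignored",
            guide_id or "<unnamed>",
            n_unannotated,
        )
    counts = Counter(annotation.assignments[g] for g in annotated)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) > top_k and ordered[top_k][1] == ordered[top_k - 1][1]:
        logger.info(
            "guide %s: tie at the top-%d boundary (count=%d) truncated lexicographically",
            guide_id or "<unnamed>",
            top_k,
            ordered[top_k][1],
        )
    return FamilyRanking(
        guide_id=guide_id,
        ranked=ordered[:top_k],
        threshold_used=threshold,
        total_annotated=len(annotated),
        n_unannotated=n_unannotated,
    )


def shared_top_families(rankings: list[FamilyRanking]) -> SharedFamilyResult:
    """Intersect top-K family sets across guides and count every Venn region."""
    if not rankings:
        raise ValueError("need at least one ranking")
    per_guide = {rk.guide_id: rk.top_families for rk in rankings}
    if len(per_guide) != len(rankings):
        raise ValueError("duplicate guide_id among rankings")
    guides = list(per_guide)
    intersection = frozenset.intersection(*per_guide.values())

    membership: dict[str, frozenset[str]] = {}
    for family in set().union(*per_guide.values()):
        membership[family] = frozenset(g for g in guides if family in per_guide[g])
    venn: dict[frozenset[str], int] = {}
    for size in range(1, len(guides) + 1):
        for combo in combinations(guides, size):
            region = frozenset(combo)
            venn[region] = sum(1 for fams in membership.values() if fams == region)
    return SharedFamilyResult(per_guide_top=per_guide, intersection=intersection, venn_counts=venn)


def write_rankings(rankings: list[FamilyRanking], path) -> None:
    """TSV with columns guide_id, rank, family, member_count."""
    rows = []
    for rk in rankings:
        for i, (family, count) in enumerate(rk.ranked, start=1):
            rows.append(
                {"guide_id": rk.guide_id, "rank": i, "family": family, "member_count": count}
            )
    pd.DataFrame.from_records(
        rows, columns=["guide_id", "rank", "family", "member_count"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
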