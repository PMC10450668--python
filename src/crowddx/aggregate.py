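"""Rank-weighted aggregation of a group's mapped differentials.

Each group member's diagnosis at rank r contributes a weight — 1/r under
the reciprocal rule, 1/r² under the squared rule, 1 under equal weighting
— and weights are summed per concept.  Concepts are sorted by total score;
tied scores are ordered by semantic-tag priority, and remaining ties by a
seeded random permutation so whole simulations are reproducible.

Scores are accumulated as exact integers scaled by lcm(1..max rank), so
tie detection is exact rather than subject to floating-point noise; the
reported scores are the familiar floats (1.5 = 1/2 + 1/1).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .mapping import DEFAULT_PRIORITY, TagPriority
from .records import CaseRecord

__all__ = [
    "RULES",
    "DiagnosisEntry",
    "CollectiveRanking",
    "score_weight",
    "aggregate",
    "top_k_contains",
    "entries_from_case",
]

RECIPROCAL = "reciprocal"
RECIPROCAL_SQUARED = "reciprocal_squared"
EQUAL = "equal"
RULES = (RECIPROCAL, RECIPROCAL_SQUARED, EQUAL)

#: accepted spellings for CLI/config convenience
RULE_ALIASES = {
    "reciprocal": RECIPROCAL,
    "1/r": RECIPROCAL,
    "reciprocal2": RECIPROCAL_SQUARED,
    "reciprocal_squared": RECIPROCAL_SQUARED,
    "1/r2": RECIPROCAL_SQUARED,
    "equal": EQUAL,
}


@dataclass(frozen=True)
class DiagnosisEntry:
    """One surviving (mapped) diagnosis of one user for one case."""

    user_id: str
    case_id: str
    rank: int
    concept_id: str

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass
class CollectiveRanking:
    """Ordered (concept, score, tag) list for one group, one rule."""

    items: list[tuple[str, float, str]]
    rule: str
    tie_seed: int

    def __len__(self) -> int:
        return len(self.items)

    @property
    def concept_ids(self) -> list[str]:
        return [cid for cid, _, _ in self.items]


def score_weight(rule: str, r: int) -> float:
    """Weight of a diagnosis at rank ``r`` under a scoring rule.

    reciprocal -> 1/r, reciprocal_squared -> 1/r², equal -> 1.
    """
    if r < 1:
        raise ValueError(f"rank must be >= 1, got {r}")
    rule = RULE_ALIASES.get(rule, rule)
    if rule == RECIPROCAL:
        return 1.0 / r
    if rule == RECIPROCAL_SQUARED:
        return 1.0 / (r * r)
    if rule == EQUAL:
        return 1.0
    raise ValueError(f"unknown rule {rule!r}")


def _tie_key(tie_seed: int, concept_id: str) -> int:
    """Deterministic pseudorandom tie-break key (independent of process hash seed)."""
    digest = hashlib.blake2b(
        f"{tie_seed}|{concept_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big")


def _integer_weights(rule: str, max_rank: int) -> tuple[dict[int, int], int]:
    """Exact integer weight per rank and the common denominator."""
    lcm = math.lcm(*range(1, max_rank + 1))
    if rule == RECIPROCAL:
        return {r: lcm // r for r in range(1, max_rank + 1)}, lcm
    if rule == RECIPROCAL_SQUARED:
        return {r: (lcm // r) ** 2 for r in range(1, max_rank + 1)}, lcm * lcm
    return {r: 1 for r in range(1, max_rank + 1)}, 1


def aggregate(
    entries: Sequence[DiagnosisEntry],
    rule: str,
    priority: TagPriority = DEFAULT_PRIORITY,
    tie_seed: int = 0,
    tags: Mapping[str, str] | None = None,
) -> CollectiveRanking:
    """Aggregate one group's entries for one case into a collective ranking.

    ``tags`` maps concept id -> semantic tag for tie-breaking; concepts
    missing from it count as "other" and lose every tag comparison.
    Singleton groups are valid — they are the individual baseline.
    """
    rule = RULE_ALIASES.get(rule, rule)
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if not entries:
        return CollectiveRanking(items=[], rule=rule, tie_seed=tie_seed)
    case_ids = {e.case_id for e in entries}
    if len(case_ids) > 1:
        raise ValueError(f"entries span multiple cases: {sorted(case_ids)}")
    tags = tags or {}

    max_rank = max(e.rank for e in entries)
    weights, denom = _integer_weights(rule, max_rank)
    totals: dict[str, int] = {}
    for e in entries:
        totals[e.concept_id] = totals.get(e.concept_id, 0) + weights[e.rank]

    ordered = sorted(
        totals,
        key=lambda cid: (
            -totals[cid],
            priority.rank(tags.get(cid, "other")),
            _tie_key(tie_seed, cid),
            cid,
        ),
    )
    items = [(cid, totals[cid] / denom, tags.get(cid, "other")) for cid in ordered]
    return CollectiveRanking(items=items, rule=rule, tie_seed=tie_seed)


def top_k_contains(ranking: CollectiveRanking, accepted: set[str], k: int) -> bool:
    """True iff any accepted concept appears among the first ``k`` entries."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not accepted:
        return False
    return any(cid in accepted for cid, _, _ in ranking.items[:k])


def entries_from_case(case: CaseRecord) -> list[DiagnosisEntry]:
    """Surviving diagnosis entries of a mapped case, deduplicated per user.

    Unmatched responses are dropped (survivors keep their original rank);
    if two of a user's diagnoses map to the same concept, only the
    best-ranked occurrence is kept so no user double-votes one concept.
    """
    best: dict[tuple[str, str], int] = {}
    for r in case.responses:
        if r.concept_id is None:
            continue
        key = (r.user_id, r.concept_id)
        if key not in best or r.rank < best[key]:
            best[key] = r.rank
    return [
        DiagnosisEntry(user_id=u, case_id=case.case_id, rank=rank, concept_id=c)
        for (u, c), rank in sorted(best.items(), key=lambda kv: (kv[0][0], kv[1]))
    ]
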