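"""Map normalized free-text diagnoses to at most one concept each.

A diagnosis matches a concept when its normalized token set equals (or,
with a relaxed threshold, is Jaccard-similar to) the token set of one of
the concept's synonyms.  When several concepts match at the accepted
similarity, the tie is broken by semantic-tag priority — diagnoses are the
goal, so "disorder" outranks "finding", which outranks "morphologic
abnormality", then "organism", then everything else.  Diagnoses matching
nothing are marked unmatched and dropped downstream; their neighbours keep
their original ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .normalize import NormalizedTerm, default_normalizer, jaccard
from .ontology import SEMANTIC_TAGS, OntologyGraph
from .records import CaseRecord

__all__ = ["TagPriority", "DEFAULT_PRIORITY", "MatchResult", "map_term", "map_case"]

MATCHED = "matched"
AMBIGUOUS = "ambiguous_resolved"
UNMATCHED = "unmatched"

_DEFAULT_ORDER = (
    "disorder",
    "finding",
    "morphologic abnormality",
    "organism",
    # tags the disambiguation step was not designed around, in fixed order
    "body structure",
    "person",
    "specimen",
    "other",
)


@dataclass(frozen=True)
class TagPriority:
    """Semantic-tag preference order used to resolve multi-concept matches."""

    order: tuple[str, ...] = _DEFAULT_ORDER

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("duplicate tags in priority order")
        missing = SEMANTIC_TAGS - set(self.order)
        if missing:
            # append any unlisted vocabulary tags in fixed (alphabetical) order
            object.__setattr__(self, "order", self.order + tuple(sorted(missing)))

    def rank(self, tag: str) -> int:
        try:
            return self.order.index(tag)
        except ValueError:
            return len(self.order)


DEFAULT_PRIORITY = TagPriority()


@dataclass(frozen=True)
class MatchResult:
    """Outcome of mapping one free-text diagnosis."""

    input_text: str
    status: str
    concept_id: str | None = None
    similarity: float = 0.0
    candidates: tuple[str, ...] = field(default_factory=tuple)

    @property
    def matched(self) -> bool:
        return self.status in (MATCHED, AMBIGUOUS)


def map_term(
    text: str,
    graph: OntologyGraph,
    priority: TagPriority = DEFAULT_PRIORITY,
    threshold: float = 1.0,
    normalizer: Callable[[str], NormalizedTerm] | None = None,
) -> MatchResult:
    """Map one raw string to at most one concept.

    At ``threshold`` 1.0 (the default, exact matching) the normalized
    token set is looked up directly in the term index.  Below 1.0 every
    index key is scanned and the candidate set is taken at the *maximal*
    Jaccard similarity >= threshold; tag priority applies only after that.
    Within one tag, ties go to the lexicographically smallest concept id,
    recorded in ``candidates`` so the choice is auditable.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not graph.term_index:
        raise ValueError("term index not built; call build_term_index first")
    if normalizer is None:
        normalizer = default_normalizer()

    tokens = normalizer(text).tokens
    if not tokens:
        return MatchResult(input_text=text, status=UNMATCHED)

    if threshold == 1.0:
        ids = graph.term_index.get(tokens, set())
        best_sim = 1.0
    else:
        best_sim = 0.0
        ids = set()
        for key, key_ids in graph.term_index.items():
            sim = jaccard(tokens, key)
            if sim < threshold:
                continue
            if sim > best_sim:
                best_sim = sim
                ids = set(key_ids)
            elif sim == best_sim:
                ids |= key_ids

    if not ids:
        return MatchResult(input_text=text, status=UNMATCHED)

    ordered = sorted(ids, key=lambda cid: (priority.rank(graph.semantic_tag(cid)), cid))
    chosen = ordered[0]
    if len(ids) == 1:
        return MatchResult(input_text=text, status=MATCHED, concept_id=chosen,
                           similarity=best_sim, candidates=(chosen,))
    return MatchResult(input_text=text, status=AMBIGUOUS, concept_id=chosen,
                       similarity=best_sim, candidates=tuple(ordered))


def map_case(
    case: CaseRecord,
    graph: OntologyGraph,
    priority: TagPriority = DEFAULT_PRIORITY,
    threshold: float = 1.0,
    normalizer: Callable[[str], NormalizedTerm] | None = None,
) -> CaseRecord:
    """Map a case's correct diagnosis and every user diagnosis.

    Returns a copy of ``case`` with mapping columns filled in.  Unmatched
    user diagnoses keep their slot but are skipped downstream, and
    surviving diagnoses retain their original rank (a survivor at rank 2
    still carries weight 1/2 under the reciprocal rule).  A case whose
    correct diagnosis cannot be mapped is flagged ``excluded``; one where
    no user diagnosis survives is flagged ``empty``.
    """
    mapped = case.copy()
    correct = map_term(case.correct_text, graph, priority, threshold, normalizer)
    mapped.correct_status = correct.status
    mapped.correct_concept_id = correct.concept_id
    mapped.excluded = not correct.matched

    any_survivor = False
    for resp in mapped.responses:
        res = map_term(resp.text, graph, priority, threshold, normalizer)
        resp.status = res.status
        resp.concept_id = res.concept_id
        resp.similarity = res.similarity if res.matched else None
        any_survivor = any_survivor or res.matched
    mapped.empty = not any_survivor
    return mapped
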