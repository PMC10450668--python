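"""SNOMED-CT-style polyhierarchical terminology: load, index, traverse.

A terminology is a set of concepts, each with an opaque identifier (the
SCTID role), a fully specified name whose trailing parenthetical is the
semantic tag ("Obstructive sleep apnea syndrome (disorder)"), a list of
synonym strings, and IS-A links to one or more parent concepts.  The IS-A
relation forms a directed acyclic graph in which multiple parents are
allowed (a polyhierarchy).

Two loaders are provided: RF2 snapshot TSV triples (concept / description
/ relationship files, active rows only) and a plain JSON list used for
fixtures and synthetic terminologies.
"""

from __future__ import annotations

import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import pandas as pd

from .normalize import NormalizedTerm, default_normalizer

__all__ = [
    "SEMANTIC_TAGS",
    "Concept",
    "OntologyGraph",
    "parse_semantic_tag",
    "load_rf2",
    "load_terminology_json",
    "save_terminology_json",
    "build_term_index",
]

logger = logging.getLogger(__name__)

#: Closed semantic-tag vocabulary; anything unrecognized becomes "other".
SEMANTIC_TAGS = frozenset(
    {
        "disorder",
        "finding",
        "morphologic abnormality",
        "body structure",
        "person",
        "organism",
        "specimen",
        "other",
    }
)

_TAG_ALIASES = {"morphological abnormality": "morphologic abnormality"}

_FSN_TAG = re.compile(r"\(([^()]+)\)\s*$")

# RF2 snapshot constants
IS_A_TYPE_ID = "116680003"
FSN_TYPE_ID = "900000000000003001"
SYNONYM_TYPE_ID = "900000000000013009"


class TerminologyError(ValueError):
    """Invalid terminology input (missing file, cyclic IS-A, bad concept)."""


def parse_semantic_tag(fsn: str) -> str:
    """Extract the semantic tag from an FSN's trailing parenthetical.

    Unrecognized or absent tags map to ``"other"``.
    """
    m = _FSN_TAG.search(fsn)
    if not m:
        return "other"
    tag = m.group(1).strip().lower()
    tag = _TAG_ALIASES.get(tag, tag)
    return tag if tag in SEMANTIC_TAGS else "other"


def strip_semantic_tag(fsn: str) -> str:
    """The FSN without its trailing parenthetical tag."""
    return _FSN_TAG.sub("", fsn).strip()


@dataclass
class Concept:
    """One terminology entry.

    ``synonyms`` includes the FSN's term (without the tag suffix) plus any
    acronyms and spelling/plural variants; every synonym refers to this
    same concept.
    """

    concept_id: str
    fsn: str
    synonyms: list[str] = field(default_factory=list)
    semantic_tag: str = "other"
    parent_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise TerminologyError("concept_id must be non-empty")
        if self.semantic_tag not in SEMANTIC_TAGS:
            raise TerminologyError(
                f"unknown semantic tag {self.semantic_tag!r} for {self.concept_id}"
            )
        if self.concept_id in self.parent_ids:
            raise TerminologyError(f"concept {self.concept_id} is its own parent")


class OntologyGraph:
    """The polyhierarchy plus a normalized-term -> concept index.

    ``term_index`` maps a frozenset of normalized tokens to the set of
    concept ids having a synonym that normalizes to that token set; it is
    populated by :func:`build_term_index`.
    """

    def __init__(self) -> None:
        self.concepts: dict[str, Concept] = {}
        self.isa_edges: set[tuple[str, str]] = set()
        self.term_index: dict[frozenset[str], set[str]] = {}
        self._children: dict[str, set[str]] = defaultdict(set)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def add_concept(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise TerminologyError(f"duplicate concept id {concept.concept_id}")
        self.concepts[concept.concept_id] = concept

    def add_edge(self, child_id: str, parent_id: str) -> bool:
        """Add an IS-A edge.  Unknown endpoints are dropped with a warning."""
        if child_id not in self.concepts or parent_id not in self.concepts:
            logger.warning("dropping IS-A edge with unknown endpoint: %s -> %s",
                           child_id, parent_id)
            return False
        if child_id == parent_id:
            raise TerminologyError(f"self-loop IS-A edge on {child_id}")
        self.isa_edges.add((child_id, parent_id))
        self.concepts[child_id].parent_ids.add(parent_id)
        self._children[parent_id].add(child_id)
        return True

    def parents(self, concept_id: str) -> set[str]:
        """Direct supertype concepts (one IS-A step up)."""
        if concept_id not in self.concepts:
            raise KeyError(concept_id)
        return set(self.concepts[concept_id].parent_ids)

    def children(self, concept_id: str) -> set[str]:
        """Direct subtype concepts (one IS-A step down)."""
        if concept_id not in self.concepts:
            raise KeyError(concept_id)
        return set(self._children.get(concept_id, set()))

    def semantic_tag(self, concept_id: str) -> str:
        return self.concepts[concept_id].semantic_tag

    def validate(self) -> None:
        """Assert structural invariants; cyclic IS-A is a hard error."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(self.isa_edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise TerminologyError(f"cyclic IS-A relation: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        """Child->parent digraph view of the IS-A relation."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(self.isa_edges)
        return g


def _read_rf2(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TerminologyError(f"RF2 file not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       quoting=3)  # QUOTE_NONE: RF2 terms may contain quotes


def load_rf2(
    concept_path: str | Path,
    description_path: str | Path,
    relationship_path: str | Path,
) -> OntologyGraph:
    """Load an RF2 snapshot (tab-separated concept/description/relationship).

    Only ``active == 1`` rows are used.  Description rows of both FSN and
    Synonym types feed the synonym list; the semantic tag is parsed from
    the FSN's trailing parenthetical.  Relationship rows whose typeId is
    the IS-A type become (child, parent) edges; edges referencing unknown
    concepts are dropped with a warning, and a cyclic IS-A relation raises
    :class:`TerminologyError`.
    """
    concepts = _read_rf2(concept_path)
    descriptions = _read_rf2(description_path)
    relationships = _read_rf2(relationship_path)

    graph = OntologyGraph()
    active_ids = set(concepts.loc[concepts["active"] == "1", "id"])

    desc = descriptions[
        (descriptions["active"] == "1") & descriptions["conceptId"].isin(active_ids)
    ]
    fsn_by_id: dict[str, str] = {}
    syns_by_id: dict[str, list[str]] = defaultdict(list)
    for row in desc.itertuples(index=False):
        if row.typeId == FSN_TYPE_ID:
            fsn_by_id[row.conceptId] = row.term
            syns_by_id[row.conceptId].append(strip_semantic_tag(row.term))
        elif row.typeId == SYNONYM_TYPE_ID:
            syns_by_id[row.conceptId].append(row.term)

    for cid in sorted(active_ids):
        fsn = fsn_by_id.get(cid, "")
        graph.add_concept(
            Concept(
                concept_id=cid,
                fsn=fsn,
                synonyms=list(dict.fromkeys(syns_by_id.get(cid, []))),
                semantic_tag=parse_semantic_tag(fsn),
            )
        )

    rel = relationships[
        (relationships["active"] == "1") & (relationships["typeId"] == IS_A_TYPE_ID)
    ]
    for row in rel.itertuples(index=False):
        graph.add_edge(row.sourceId, row.destinationId)

    graph.validate()
    return graph


def load_terminology_json(path: str | Path) -> OntologyGraph:
    """Load the plain JSON terminology dialect.

    The file is a list of ``{"id", "fsn", "tag"?, "synonyms", "parents"}``
    objects; ``tag`` defaults to the FSN's parenthetical suffix.
    """
    path = Path(path)
    if not path.exists():
        raise TerminologyError(f"terminology file not found: {path}")
    entries = json.loads(path.read_text())
    return terminology_from_records(entries)


def terminology_from_records(entries: Iterable[dict]) -> OntologyGraph:
    graph = OntologyGraph()
    entries = list(entries)
    for e in entries:
        fsn = e.get("fsn", "")
        tag = e.get("tag") or parse_semantic_tag(fsn)
        tag = _TAG_ALIASES.get(tag, tag)
        synonyms = list(e.get("synonyms", []))
        if fsn and strip_semantic_tag(fsn) not in synonyms:
            synonyms.insert(0, strip_semantic_tag(fsn))
        graph.add_concept(
            Concept(concept_id=str(e["id"]), fsn=fsn, synonyms=synonyms,
                    semantic_tag=tag)
        )
    for e in entries:
        for pid in e.get("parents", []):
            graph.add_edge(str(e["id"]), str(pid))
    graph.validate()
    return graph


def save_terminology_json(graph: OntologyGraph, path: str | Path) -> None:
    records = [
        {
            "id": c.concept_id,
            "fsn": c.fsn,
            "tag": c.semantic_tag,
            "synonyms": c.synonyms,
            "parents": sorted(c.parent_ids),
        }
        for c in graph.concepts.values()
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def build_term_index(
    graph: OntologyGraph,
    normalizer: Callable[[str], NormalizedTerm] | None = None,
) -> OntologyGraph:
    """Populate ``graph.term_index`` from every synonym of every concept.

    Each synonym contributes one entry keyed by its normalized token set;
    distinct concepts sharing a normalized synonym land in the same
    multi-valued entry (the ambiguity path).  Synonyms that normalize to
    the empty set are skipped with a warning.
    """
    if normalizer is None:
        normalizer = default_normalizer()
    index: dict[frozenset[str], set[str]] = defaultdict(set)
    for concept in graph.concepts.values():
        for syn in concept.synonyms:
            key = normalizer(syn).tokens
            if not key:
                logger.warning("synonym %r of %s normalizes to nothing; skipped",
                               syn, concept.concept_id)
                continue
            index[key].add(concept.concept_id)
    graph.term_index = dict(index)
    return graph
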