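"""Synthetic terminologies and diagnostician cohorts.

Real inputs to this pipeline — a licensed SNOMED CT release and the
proprietary Human Dx-style response data — cannot be redistributed, so
this module generates miniature stand-ins that reproduce the statistical
structure the method depends on:

* a polyhierarchical terminology (multi-parent IS-A DAG) whose concepts
  carry synonym variants (acronym, British spelling, plural) plus one
  deliberately ambiguous synonym shared by a disorder / morphologic
  abnormality pair, exercising the tag-priority disambiguation path;
* cohorts of ~10 ranked differentials per case in which rank-1 entries
  are more often correct than lower ranks (rank-conditional correctness
  p_1 > p_2 > ...), a fraction q of incorrect entries are parent/child
  near-misses of the correct concept, and a fraction u of entries are
  unmatchable free text.

All generation is reproducible from (spec, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .normalize import default_normalizer
from .ontology import Concept, OntologyGraph, build_term_index
from .records import CaseRecord, Response

__all__ = ["CohortSpec", "generate_ontology", "generate_cohort", "AMBIGUOUS_NAME"]

_ADJECTIVES = [
    "acute", "chronic", "nodular", "cystic", "fibrous", "diffuse", "focal",
    "spastic", "septic", "benign", "malignant", "atypical", "juvenile",
    "recurrent", "lateral", "medial", "cortical", "spinal", "renal",
    "hepatic", "cardiac", "gastric", "dermal", "ocular", "neural",
    "vascular", "lymphoid", "mucosal", "serous", "pleural", "tracheal",
    "bronchial", "aortic", "venous", "arterial", "femoral", "cranial",
    "pelvic", "thoracic", "lumbar",
]
_NOUNS = [
    "stenosis", "fibrosis", "necrosis", "sclerosis", "atrophy", "dystrophy",
    "carcinoma", "sarcoma", "adenoma", "lipoma", "ulcer", "lesion",
    "abscess", "polyp", "nodule", "tumor", "edema", "anemia", "dermatitis",
    "nephritis", "hepatitis", "colitis", "gastritis", "arthritis",
    "myopathy", "neuropathy", "embolism", "thrombosis", "aneurysm",
    "infarction", "occlusion", "rupture", "fracture", "palsy", "hemorrhage",
    "ischemia", "hematoma", "leukemia", "cyst", "granuloma",
]

# US -> British spellings available for variant synonyms (inverse of the
# normalization table, restricted to nouns in the pool above)
_US_TO_BRITISH = {
    "anemia": "anaemia",
    "edema": "oedema",
    "tumor": "tumour",
    "hemorrhage": "haemorrhage",
    "ischemia": "ischaemia",
    "hematoma": "haematoma",
    "leukemia": "leukaemia",
}

#: shared synonym of the planted ambiguous concept pair
AMBIGUOUS_NAME = "kaposi sarcoma"

_TAG_CHOICES = ["disorder", "finding", "morphologic abnormality", "organism"]
_TAG_WEIGHTS = [0.70, 0.15, 0.10, 0.05]

_TENURE_LEVELS = ["medical student", "intern", "resident", "fellow",
                  "attending physician"]
# observed tenure mix of unique diagnoses: 23/10/40/1/26 percent
_TENURE_WEIGHTS = [0.23, 0.10, 0.40, 0.01, 0.26]

_SPECIALTIES = ["cardiology", "dermatology", "endocrinology", "neurology",
                "infectious disease", "gastroenterology"]
_COMPLAINTS = ["chest pain", "fever", "headache", "fatigue", "abdominal pain"]


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for a synthetic terminology + cohort.

    The defaults encode the study conditions the generator emulates:
    10 diagnosticians per case, differentials of 1-5 entries, rank-1
    entries most likely correct (p_r decreasing), ~13% unmatchable free
    text, and a substantial parent/child near-miss fraction.
    """

    # terminology shape
    n_concepts: int = 60
    depth: int = 4
    branching: float = 2.5
    multi_parent_rate: float = 0.3
    acronym_rate: float = 0.3
    british_rate: float = 0.5
    plural_rate: float = 0.3
    # cohort shape
    n_cases: int = 200
    n_users_per_case: int = 10
    max_differential: int = 5
    length_continuation: float = 0.55  # truncated-geometric length on 1..max
    p_r: tuple[float, ...] = (0.45, 0.25, 0.15, 0.10, 0.08)
    near_miss_rate: float = 0.15
    unmatched_rate: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 10 or self.depth < 2:
            raise ValueError("need n_concepts >= 10 and depth >= 2")
        if len(self.p_r) < self.max_differential:
            raise ValueError("p_r must cover every rank up to max_differential")
        if any(not 0 <= p <= 1 for p in self.p_r):
            raise ValueError("p_r values must be probabilities")
        if list(self.p_r) != sorted(self.p_r, reverse=True):
            raise ValueError("p_r must be non-increasing (rank-1 most accurate)")
        for r, p in enumerate(self.p_r[: self.max_differential], start=1):
            if p + self.near_miss_rate + self.unmatched_rate > 1 + 1e-12:
                raise ValueError(
                    f"p_{r} + near-miss + unmatched exceeds 1 at rank {r}"
                )


def _pluralize(noun: str) -> str:
    if noun.endswith(("is", "us", "s")):
        return noun
    if noun.endswith("y"):
        return noun[:-1] + "ies"
    return noun + "s"


def generate_ontology(spec: CohortSpec) -> OntologyGraph:
    """Build a synthetic polyhierarchical terminology.

    Concepts are adjective+noun pairs arranged in ``depth`` layers under a
    single root; each non-root concept gets one parent in the layer above
    and, at ``multi_parent_rate`` (floor 10% overall), a second one.
    Synonym variants are added at the spec's rates, and the ambiguous
    disorder / morphologic-abnormality pair is always planted.
    """
    rng = random.Random(spec.seed)
    normalizer = default_normalizer()
    graph = OntologyGraph()

    pairs = [(a, n) for a in _ADJECTIVES for n in _NOUNS]
    rng.shuffle(pairs)

    used_keys: set[frozenset[str]] = set()

    def reserve(text: str) -> frozenset[str] | None:
        key = normalizer(text).tokens
        if not key or key in used_keys:
            return None
        used_keys.add(key)
        return key

    root_id = "1000000"
    reserve("clinical finding")
    graph.add_concept(Concept(root_id, "Clinical finding (finding)",
                              ["Clinical finding"], "finding"))

    # distribute concepts over layers with geometric growth
    n_rest = spec.n_concepts - 1
    raw = [spec.branching ** lvl for lvl in range(spec.depth)]
    sizes = [max(1, round(n_rest * w / sum(raw))) for w in raw]
    while sum(sizes) > n_rest:
        sizes[sizes.index(max(sizes))] -= 1
    while sum(sizes) < n_rest:
        sizes[-1] += 1

    layers: list[list[str]] = [[root_id]]
    next_id = 1000001
    pair_iter = iter(pairs)
    for size in sizes:
        layer: list[str] = []
        for _ in range(size):
            name = key = None
            for adj, noun in pair_iter:
                name = f"{adj} {noun}"
                key = reserve(name)
                if key is not None:
                    break
            if key is None:
                raise ValueError("word pool exhausted; lower n_concepts")
            cid = str(next_id)
            next_id += 1
            tag = rng.choices(_TAG_CHOICES, weights=_TAG_WEIGHTS, k=1)[0]
            synonyms = [name.title()]
            adj, noun = name.split()
            if rng.random() < spec.acronym_rate:
                acr = (adj[0] + noun[0]).upper()
                synonyms.append(f"{acr}—{name}")  # "AN—acute nephritis" style
                if reserve(acr) is not None:
                    synonyms.append(acr)
            if noun in _US_TO_BRITISH and rng.random() < spec.british_rate:
                synonyms.append(f"{adj} {_US_TO_BRITISH[noun]}")
            plural = _pluralize(noun)
            if plural != noun and rng.random() < spec.plural_rate:
                synonyms.append(f"{adj} {plural}")
            graph.add_concept(Concept(cid, f"{name.title()} ({tag})", synonyms, tag))
            layer.append(cid)
        layers.append(layer)

    # parent links: one guaranteed, a second at multi_parent_rate
    for prev, layer in zip(layers, layers[1:]):
        for cid in layer:
            parent = rng.choice(prev)
            graph.add_edge(cid, parent)
            if len(prev) > 1 and rng.random() < spec.multi_parent_rate:
                second = rng.choice([p for p in prev if p != parent])
                graph.add_edge(cid, second)

    # enforce a genuine polyhierarchy: >= 10% of non-root concepts multi-parent
    non_root = [c for c in graph.concepts.values() if c.concept_id != root_id]
    need = -(-len(non_root) * 10 // 100)  # ceil(10%)
    deficient = [c for c in non_root if len(c.parent_ids) < 2]
    have = len(non_root) - len(deficient)
    rng.shuffle(deficient)
    for c in deficient:
        if have >= need:
            break
        # choose an extra parent from the layer above this concept's layer
        lvl = next(i for i, layer in enumerate(layers) if c.concept_id in layer)
        options = [p for p in layers[lvl - 1] if p not in c.parent_ids]
        if options:
            graph.add_edge(c.concept_id, rng.choice(options))
            have += 1

    # planted ambiguous pair: same normalized synonym, different tags
    amb_parents = [rng.choice(layers[1]), rng.choice(layers[1])]
    for tag, parent in zip(["disorder", "morphologic abnormality"], amb_parents):
        cid = str(next_id)
        next_id += 1
        graph.add_concept(
            Concept(cid, f"{AMBIGUOUS_NAME.title()} ({tag})",
                    [AMBIGUOUS_NAME.title()], tag)
        )
        graph.add_edge(cid, parent)

    graph.validate()
    build_term_index(graph, normalizer)
    return graph


def ambiguous_pair(graph: OntologyGraph) -> set[str]:
    """Concept ids sharing the planted ambiguous synonym."""
    key = default_normalizer()(AMBIGUOUS_NAME).tokens
    return set(graph.term_index.get(key, set()))


def _noisy(text: str, rng: random.Random) -> str:
    """Surface noise that normalization must undo (case, punctuation, spacing)."""
    style = rng.randrange(6)
    if style == 0:
        text = text.lower()
    elif style == 1:
        text = text.upper()
    elif style == 2:
        text = text.capitalize()
    elif style == 3:
        text = text + "."
    elif style == 4:
        text = " " + text + " "
    return text


def _gibberish(rng: random.Random, graph: OntologyGraph) -> str:
    consonants = "bcdfghjklmnpqrstvwxz"
    norm = default_normalizer()
    while True:
        text = " ".join(
            "".join(rng.choice(consonants) for _ in range(rng.randint(5, 9)))
            for _ in range(rng.randint(1, 2))
        )
        if norm(text).tokens not in graph.term_index:
            return text


def _distractor_pool(graph: OntologyGraph, correct: str,
                     exclude: set[str]) -> list[str]:
    """Plausible wrong answers: the radius-3 graph neighborhood of the
    correct concept, never the correct concept itself or its direct
    parents/children (those are near-misses, drawn separately)."""
    undirected = {}
    for child, parent in graph.isa_edges:
        undirected.setdefault(child, set()).add(parent)
        undirected.setdefault(parent, set()).add(child)
    frontier = {correct}
    seen = {correct}
    for _ in range(3):
        frontier = {n for f in frontier for n in undirected.get(f, set())} - seen
        seen |= frontier
    family = {correct} | graph.parents(correct) | graph.children(correct)
    pool = sorted(seen - family - exclude)
    if len(pool) < 8:  # tiny neighborhoods fall back to the whole terminology
        pool = sorted(set(graph.concepts) - family - exclude)
    return pool


def generate_cohort(graph: OntologyGraph, spec: CohortSpec) -> list[CaseRecord]:
    """Generate raw-text cases and ranked differentials over ``graph``.

    Each rank-r slot of each differential is, independently, the correct
    concept with probability p_r, a direct parent/child near-miss with
    probability q, unmatchable gibberish with probability u, and otherwise
    a wrong concept from the correct concept's graph neighborhood.  Texts
    are emitted through a randomly chosen synonym with surface noise.  A
    user may occasionally repeat a concept across ranks; mapping keeps the
    best-ranked occurrence.
    """
    rng = random.Random(spec.seed + 1_000_003)
    amb = ambiguous_pair(graph)
    candidates = sorted(
        cid for cid in graph.concepts
        if cid not in amb and graph.parents(cid) and graph.children(cid)
    )
    if not candidates:
        raise ValueError("terminology has no internal concepts to use as answers")

    cases: list[CaseRecord] = []
    for i in range(spec.n_cases):
        correct = rng.choice(candidates)
        near = sorted(graph.parents(correct) | graph.children(correct))
        pool = _distractor_pool(graph, correct, exclude=amb)

        def emit(cid: str) -> str:
            return _noisy(rng.choice(graph.concepts[cid].synonyms), rng)

        responses: list[Response] = []
        for u in range(spec.n_users_per_case):
            tenure = rng.choices(_TENURE_LEVELS, weights=_TENURE_WEIGHTS, k=1)[0]
            length = 1
            while (length < spec.max_differential
                   and rng.random() < spec.length_continuation):
                length += 1
            for r in range(1, length + 1):
                roll = rng.random()
                p = spec.p_r[r - 1]
                if roll < p:
                    text = emit(correct)
                elif roll < p + spec.near_miss_rate:
                    text = emit(rng.choice(near))
                elif roll < p + spec.near_miss_rate + spec.unmatched_rate:
                    text = _gibberish(rng, graph)
                else:
                    text = emit(rng.choice(pool))
                responses.append(
                    Response(user_id=f"u{u + 1:03d}", rank=r, text=text,
                             tenure=tenure)
                )
        cases.append(
            CaseRecord(
                case_id=f"case{i + 1:04d}",
                correct_text=emit(correct),
                responses=responses,
                specialty=rng.choice(_SPECIALTIES),
                chief_complaint=rng.choice(_COMPLAINTS),
            )
        )
    return cases
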