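import pytest

from crowddx import (
    CohortSpec,
    build_term_index,
    demo_inputs,
    generate_cohort,
    generate_ontology,
    map_case,
)
from crowddx.ontology import Concept, OntologyGraph


def make_graph(entries):
    """Build a small graph from (id, fsn, tag, synonyms, parents) tuples."""
    g = OntologyGraph()
    for cid, fsn, tag, synonyms, _ in entries:
        g.add_concept(Concept(cid, fsn, list(synonyms), tag))
    for cid, _, _, _, parents in entries:
        for pid in parents:
            g.add_edge(cid, pid)
    g.validate()
    return build_term_index(g)


@pytest.fixture
def diamond_graph():
    """A at the top, B and C below it, D with both B and C as parents."""
    return make_graph(
        [
            ("A", "Apex disease (disorder)", "disorder", ["apex disease"], []),
            ("B", "Left variant (disorder)", "disorder", ["left variant"], ["A"]),
            ("C", "Right variant (disorder)", "disorder", ["right variant"], ["A"]),
            ("D", "Deep variant (disorder)", "disorder", ["deep variant"], ["B", "C"]),
        ]
    )


@pytest.fixture(scope="session")
def sleep_fixture():
    """The bundled obstructive-sleep-apnea micro-case (terminology + 1 case)."""
    return demo_inputs()


@pytest.fixture(scope="session")
def synth_graph():
    return generate_ontology(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def mapped_cohort(synth_graph):
    """A small mapped synthetic cohort shared by the slower tests."""
    spec = CohortSpec(seed=7, n_cases=30)
    cases = generate_cohort(synth_graph, spec)
    return [map_case(c, synth_graph) for c in cases], synth_graph, spec
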