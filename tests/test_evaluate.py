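"""Group enumeration, hierarchy credit, and the accuracy simulation."""

import math

import pytest

from crowddx import SimulationConfig, accepted_set, enumerate_groups, simulate
from crowddx.evaluate import sample_groups
from crowddx.records import CaseRecord, Response

from conftest import make_graph
import random


@pytest.mark.parametrize(
    ("n", "k", "expected"),
    [(10, 10, 1), (10, 1, 10), (10, 5, 252), (4, 2, 6)],
)
def test_enumerate_groups_counts(n, k, expected):
    users = [f"u{i}" for i in range(n)]
    groups = enumerate_groups(users, k)
    assert len(groups) == expected == math.comb(n, k)
    assert len(set(groups)) == len(groups)
    assert all(g == tuple(sorted(g)) for g in groups)


def test_enumerate_groups_rejects_oversized_k():
    with pytest.raises(ValueError):
        enumerate_groups(["u1", "u2"], 3)


def test_sample_groups_seeded_and_distinct():
    users = [f"u{i}" for i in range(8)]
    a = sample_groups(users, 3, 10, random.Random(5))
    b = sample_groups(users, 3, 10, random.Random(5))
    assert a == b and len(set(a)) == 10


def test_accepted_set_modes(diamond_graph):
    assert accepted_set("D", diamond_graph, "exact") == {"D"}
    assert accepted_set("D", diamond_graph, "exact+parents") == {"D", "B", "C"}
    assert accepted_set("B", diamond_graph, "exact+children") == {"B", "D"}
    assert accepted_set("B", diamond_graph, "exact+both") == {"B", "A", "D"}
    for cid in diamond_graph.concepts:
        exact = accepted_set(cid, diamond_graph, "exact")
        par = accepted_set(cid, diamond_graph, "exact+parents")
        both = accepted_set(cid, diamond_graph, "exact+both")
        assert exact <= par <= both
    with pytest.raises(KeyError):
        accepted_set("nope", diamond_graph, "exact")


def _mapped_case(case_id, correct, user_concepts, graph, tenure=None):
    """Build an already-mapped case: user_concepts is {user: [concepts by rank]}."""
    responses = []
    for user, concepts in user_concepts.items():
        for r, cid in enumerate(concepts, start=1):
            resp = Response(user_id=user, rank=r, text=cid,
                            tenure=(tenure or {}).get(user))
            resp.concept_id = cid
            resp.status = "matched"
            resp.similarity = 1.0
            responses.append(resp)
    case = CaseRecord(case_id=case_id, correct_text=correct, responses=responses)
    case.correct_concept_id = correct
    case.correct_status = "matched"
    return case


@pytest.fixture
def flat_graph():
    return make_graph(
        [("root", "Root (disorder)", "disorder", ["root"], [])]
        + [
            (c, f"{c.title()} (disorder)", "disorder", [c], ["root"])
            for c in ("good", "bad1", "bad2", "bad3")
        ]
    )


def test_unanimous_groups_are_always_right(flat_graph):
    cases = [
        _mapped_case("c1", "good",
                     {"u1": ["good", "bad1"], "u2": ["good", "bad2"]}, flat_graph)
    ]
    res = simulate(cases, flat_graph,
                   SimulationConfig(group_sizes=(1, 2), rules=("reciprocal",)))
    assert (res["accuracy"] == 1.0).all()


def test_three_way_tie_breaks_uniformly(flat_graph):
    """correct@1 vs two distinct wrong@1: all tied at 1.0; over many seeds the
    correct concept wins the top-1 slot about a third of the time."""
    cases = [
        _mapped_case("c1", "good",
                     {"u1": ["good"], "u2": ["bad1"], "u3": ["bad2"]}, flat_graph)
    ]
    hits = 0
    n = 400
    for seed in range(n):
        res = simulate(
            cases, flat_graph,
            SimulationConfig(group_sizes=(3,), rules=("reciprocal",),
                             top_k=(1,), seed=seed),
        )
        hits += res["accuracy"].iloc[0]
    assert abs(hits / n - 1 / 3) < 0.08


def test_topk_monotone_and_hierarchy_dominance(mapped_cohort):
    cases, graph, _ = mapped_cohort
    res = simulate(
        cases, graph,
        SimulationConfig(group_sizes=(1, 3, 5), rules=("reciprocal",),
                         match_modes=("exact", "exact+parents",
                                      "exact+children", "exact+both"),
                         seed=11),
    )
    pivot = res.pivot_table(index=["group_size", "rule", "match_mode"],
                            columns="top_k", values="accuracy")
    assert (pivot[1] <= pivot[2]).all() and (pivot[2] <= pivot[3]).all()
    modes = res.pivot_table(index=["group_size", "rule", "top_k"],
                            columns="match_mode", values="accuracy")
    for widened in ("exact+parents", "exact+children", "exact+both"):
        assert (modes["exact"] <= modes[widened]).all()
    assert (modes["exact+parents"] <= modes["exact+both"]).all()
    assert (modes["exact+children"] <= modes["exact+both"]).all()


def test_sampled_enumeration_approximates_exhaustive(mapped_cohort):
    cases, graph, _ = mapped_cohort
    base = SimulationConfig(group_sizes=(4,), rules=("reciprocal",), top_k=(3,),
                            seed=3)
    exact = simulate(cases, graph, base)["accuracy"].iloc[0]
    sampled = simulate(
        cases, graph,
        SimulationConfig(group_sizes=(4,), rules=("reciprocal",), top_k=(3,),
                         seed=3, sample_groups=60),
    )["accuracy"].iloc[0]
    # C(10,4)=210 groups exhaustive vs 60 sampled per case
    assert abs(exact - sampled) < 0.05


def test_cases_smaller_than_group_size_are_skipped(flat_graph):
    cases = [
        _mapped_case("small", "good", {"u1": ["good"], "u2": ["good"]}, flat_graph),
        _mapped_case("big", "good",
                     {f"u{i}": ["good"] for i in range(5)}, flat_graph),
    ]
    res = simulate(cases, flat_graph,
                   SimulationConfig(group_sizes=(2, 4), rules=("reciprocal",),
                                    top_k=(1,)))
    n_cases = res.set_index("group_size")["n_cases"]
    assert n_cases[2] == 2 and n_cases[4] == 1


def test_specialty_stratification(flat_graph):
    cases = [
        _mapped_case("c1", "good", {"u1": ["good"], "u2": ["good"]}, flat_graph),
        _mapped_case("c2", "good", {"u1": ["bad1"], "u2": ["bad1"]}, flat_graph),
    ]
    cases[0].specialty = "cardiology"
    cases[1].specialty = "neurology"
    res = simulate(cases, flat_graph,
                   SimulationConfig(group_sizes=(2,), rules=("reciprocal",),
                                    top_k=(1,), stratify_by="specialty"))
    acc = res.set_index("stratum")["accuracy"]
    assert acc["cardiology"] == 1.0 and acc["neurology"] == 0.0


def test_tenure_stratification_is_within_case(flat_graph):
    """Only cases with enough users of every tenure level enter, and groups
    are drawn within one tenure level at a time."""
    tenure = {}
    user_concepts = {}
    for i in range(3):
        u = f"s{i}"; tenure[u] = "medical student"; user_concepts[u] = ["bad1"]
    for i in range(3):
        u = f"r{i}"; tenure[u] = "resident"; user_concepts[u] = ["good"]
    for i in range(3):
        u = f"a{i}"; tenure[u] = "attending physician"; user_concepts[u] = ["good"]
    rich = _mapped_case("rich", "good", user_concepts, flat_graph, tenure=tenure)
    poor = _mapped_case("poor", "good", {"u1": ["good"]}, flat_graph,
                        tenure={"u1": "resident"})
    res = simulate([rich, poor], flat_graph,
                   SimulationConfig(group_sizes=(1, 3), rules=("reciprocal",),
                                    top_k=(1,), stratify_by="tenure"))
    assert (res["n_cases"] == 1).all()  # the poor case never qualifies
    acc = res.set_index(["stratum", "group_size"])["accuracy"]
    assert acc[("medical student", 3)] == 0.0
    assert acc[("resident", 3)] == 1.0
    assert acc[("attending physician", 1)] == 1.0


def test_simulate_rejects_empty_input(flat_graph):
    with pytest.raises(ValueError):
        simulate([], flat_graph, SimulationConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(rules=("median",))
    with pytest.raises(ValueError):
        SimulationConfig(match_modes=("fuzzy",))
    with pytest.raises(ValueError):
        SimulationConfig(sample_groups=0)
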