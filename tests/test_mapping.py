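"""Concept mapping: exact/relaxed matching and tag-priority disambiguation."""

import pytest

from crowddx import TagPriority, map_case, map_term
from crowddx.mapping import AMBIGUOUS, MATCHED, UNMATCHED
from crowddx.records import CaseRecord, Response
from crowddx.synthetic import ambiguous_pair

from conftest import make_graph


@pytest.fixture
def kaposi_graph():
    return make_graph(
        [
            ("93616000", "Kaposi's sarcoma (disorder)", "disorder",
             ["Kaposi's sarcoma"], []),
            ("35411000", "Kaposi's sarcoma, morphology (morphologic abnormality)",
             "morphologic abnormality", ["Kaposi's sarcoma"], []),
        ]
    )


class TestMapTerm:
    def test_synonyms_reach_the_same_concept(self, sleep_fixture):
        graph, _ = sleep_fixture
        for text in ("OSA—obstructive sleep apnea", "obstructive sleep apnea",
                     "O.S.A.", "osa"):
            res = map_term(text, graph)
            assert res.status == MATCHED
            assert res.concept_id == "78275009"
            assert res.similarity == 1.0

    def test_substring_points_to_different_concept(self, sleep_fixture):
        graph, _ = sleep_fixture
        # "sleep apnea" is its own concept, not the obstructive one
        assert map_term("sleep apnea", graph).concept_id == "73430006"

    def test_unmatched_text(self, sleep_fixture):
        graph, _ = sleep_fixture
        res = map_term("circadian rhythm sleep disorder", graph)
        assert res.status == UNMATCHED
        assert res.concept_id is None

    def test_empty_text_is_unmatched_not_error(self, sleep_fixture):
        graph, _ = sleep_fixture
        assert map_term("  .. ", graph).status == UNMATCHED

    def test_ambiguity_resolved_by_tag_priority(self, kaposi_graph):
        res = map_term("Kaposi's sarcoma", kaposi_graph)
        assert res.status == AMBIGUOUS
        assert res.concept_id == "93616000"  # the (disorder) concept wins
        assert set(res.candidates) == {"93616000", "35411000"}

    def test_custom_priority_can_flip_the_choice(self, kaposi_graph):
        prio = TagPriority(order=("morphologic abnormality", "disorder", "finding",
                                  "organism"))
        assert map_term("Kaposi's sarcoma", kaposi_graph, priority=prio).concept_id == "35411000"

    def test_within_tag_tie_breaks_to_smallest_id(self):
        g = make_graph(
            [
                ("200", "Twin alpha (disorder)", "disorder", ["shared name"], []),
                ("100", "Twin beta (disorder)", "disorder", ["shared name"], []),
            ]
        )
        res = map_term("shared name", g)
        assert res.status == AMBIGUOUS
        assert res.concept_id == "100"

    def test_relaxed_threshold_takes_maximal_similarity(self, sleep_fixture):
        graph, _ = sleep_fixture
        # {obstructive, apnea}: 2/3 against "obstructive sleep apnea",
        # 1/2 against the dashed synonym -> the 2/3 candidate wins
        res = map_term("obstructive apnea", graph, threshold=0.5)
        assert res.concept_id == "78275009"
        assert res.similarity == pytest.approx(2 / 3)

    def test_lower_threshold_never_loses_matches(self, sleep_fixture):
        graph, _ = sleep_fixture
        probes = ["obstructive apnea", "sleep apnea", "osa", "narcolepsy attack",
                  "zzzz", "insomnia"]
        matched = {}
        for thr in (1.0, 0.6, 0.4):
            matched[thr] = sum(map_term(t, graph, threshold=thr).matched
                               for t in probes)
        assert matched[1.0] <= matched[0.6] <= matched[0.4]

    def test_threshold_validation(self, sleep_fixture):
        graph, _ = sleep_fixture
        with pytest.raises(ValueError):
            map_term("osa", graph, threshold=0.0)
        with pytest.raises(ValueError):
            map_term("osa", graph, threshold=1.5)

    def test_synonym_round_trip_over_synthetic_terminology(self, synth_graph):
        """Every generated synonym maps back to its own concept at threshold 1,
        except the planted ambiguous pair, which resolves by tag priority."""
        amb = ambiguous_pair(synth_graph)
        for concept in synth_graph.concepts.values():
            for syn in concept.synonyms:
                res = map_term(syn, synth_graph)
                assert res.matched
                if concept.concept_id in amb:
                    assert res.concept_id in amb
                    assert synth_graph.semantic_tag(res.concept_id) == "disorder"
                else:
                    assert res.concept_id == concept.concept_id


class TestMapCase:
    def make_case(self, responses, correct="Obstructive sleep apnea"):
        return CaseRecord(case_id="c1", correct_text=correct, responses=responses)

    def test_survivors_retain_original_rank(self, sleep_fixture):
        graph, _ = sleep_fixture
        case = self.make_case(
            [
                Response("u1", 1, "utterly unmappable junk"),
                Response("u1", 2, "obstructive sleep apnea"),
            ]
        )
        mapped = map_case(case, graph)
        assert not mapped.excluded and not mapped.empty
        survivor = mapped.responses[1]
        assert survivor.concept_id == "78275009" and survivor.rank == 2
        from crowddx import entries_from_case, score_weight
        (entry,) = entries_from_case(mapped)
        assert entry.rank == 2
        assert score_weight("reciprocal", entry.rank) == 0.5

    def test_case_with_unmatched_correct_is_excluded(self, sleep_fixture):
        graph, _ = sleep_fixture
        case = self.make_case(
            [Response("u1", 1, "sleep apnea")], correct="no such diagnosis",
        )
        mapped = map_case(case, graph)
        assert mapped.excluded
        assert mapped.correct_concept_id is None

    def test_all_users_unmatched_flags_empty(self, sleep_fixture):
        graph, _ = sleep_fixture
        case = self.make_case(
            [Response("u1", 1, "gibberish one"), Response("u2", 1, "gibberish two")]
        )
        assert map_case(case, graph).empty

    def test_duplicate_concept_keeps_best_rank(self, sleep_fixture):
        graph, _ = sleep_fixture
        from crowddx import entries_from_case
        case = self.make_case(
            [
                Response("u1", 1, "osa"),
                Response("u1", 3, "OSA—obstructive sleep apnea"),
                Response("u1", 2, "narcolepsy"),
            ]
        )
        entries = entries_from_case(map_case(case, graph))
        by_concept = {e.concept_id: e.rank for e in entries}
        assert by_concept["78275009"] == 1  # not double-voted at rank 3
        assert by_concept["60380001"] == 2

    def test_determinism(self, sleep_fixture):
        graph, cases = sleep_fixture
        a = map_case(cases[0], graph)
        b = map_case(cases[0], graph)
        assert [(r.concept_id, r.status) for r in a.responses] == [
            (r.concept_id, r.status) for r in b.responses
        ]
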