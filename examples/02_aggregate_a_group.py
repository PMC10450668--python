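"""Aggregate a group's ranked differentials into a collective ranking.

Three diagnosticians each submit a ranked list for the bundled case.
Under the reciprocal rule a diagnosis at rank r contributes 1/r; the
correct concept, reported at rank 2 by one user and rank 1 by another,
accumulates 1/2 + 1/1 = 1.5 and tops the collective ranking.
"""

from crowddx import aggregate, demo_inputs, entries_from_case, map_case

graph, cases = demo_inputs()
case = map_case(cases[0], graph)
print(f"correct diagnosis {case.correct_text!r} -> concept {case.correct_concept_id}")

entries = entries_from_case(case)
ranking = aggregate(
    entries, "reciprocal",
    tags={cid: graph.semantic_tag(cid) for cid in graph.concepts},
)
for pos, (cid, score, tag) in enumerate(ranking.items, start=1):
    marker = "  <- correct" if cid == case.correct_concept_id else ""
    print(f"#{pos}  {cid}  score={score:.3f}  ({tag}){marker}")

# Scores are summed 1/r weights across group members; the sort is by
# score, then semantic-tag priority, then a seeded random shuffle.
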