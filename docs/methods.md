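# Methods

## Problem and model

Open-ended diagnostics has no fixed answer set: each diagnostician
submits a ranked list of free-text diagnoses (a differential), and two
submissions naming the same disease may differ in spelling, number,
punctuation, or acronym use. crowddx makes such answers commensurable by
linking every submission to a concept in a polyhierarchical terminology
and then aggregates at the concept level.

The aggregation model is a rank-weighted vote. For a group G of
diagnosticians, the collective support of concept c is

    S(c) = Σ_{u ∈ G} Σ_{r : concept(u, r) = c} w(r)

with w(r) = 1/r (reciprocal rule), 1/r² (reciprocal squared) or 1 (equal
weighting). The collective ranking sorts concepts by S(c) descending.
The group is judged correct at cutoff k if an accepted concept appears
in the top k. The accepted set is {correct} for exact matching, and can
be widened with the correct concept's direct IS-A parents and/or
children (hierarchy credit). Parent/child means one IS-A step; the
conservative single-step reading is the default, since near-miss credit
loses its clinical meaning as the path length grows.

## Normalization and matching

The normalization cascade is: lowercase → strip possessives and
punctuation (hyphens, dashes and slashes become token separators;
periods and apostrophes are deleted so "O.S.A." → "osa") → tokenize →
drop stop words → per-token British→US spelling → per-token
singularization → deduplicate into a set. Design points:

- **Stop words** are a deliberately short, clinically safe list
  (articles, prepositions, conjunctions). Words like "acute" or "right"
  are never stop words: deleting them would merge distinct diagnoses.
- **Spelling** is a token-level lookup table rather than a locale-aware
  spell checker: deterministic and auditable. The table is applied
  before *and* after singularization, so plural British forms
  ("anaemias") still reach their US singular ("anemia").
- **Singularization** is rule-based; tokens of ≤ 3 characters are exempt
  (protects acronyms), as are -us/-is/-ss endings and a short invariant
  list ("diabetes", "feces", ...). No stemming beyond this: "ischemic"
  and "ischemia" intentionally stay distinct tokens.
- **Acronyms** are resolved through the terminology itself: synonym
  lists ship entries like "OSA—obstructive sleep apnea", so a user's
  "osa" matches via the indexed synonym. The package maintains no
  acronym-expansion dictionary of its own.
- Matching is **exact by default** (Jaccard 1 on token sets). A relaxed
  threshold t < 1 accepts the candidate set at *maximal* similarity ≥ t
  before tag priority applies. There is deliberately no typo tolerance:
  exactness guarantees that a match is never an introduced error.
- **Ambiguity** (one string, several concepts) is resolved by semantic
  tag priority: disorder, finding, morphologic abnormality, organism,
  then the remaining tags in fixed order. Within one tag the
  lexicographically smallest concept id wins, and all tied candidates
  are recorded in the MatchResult so the choice is auditable.
- After discarding unmatched entries, survivors **keep their original
  rank** (a survivor at rank 2 still weighs 1/2): the submitted rank
  encodes the diagnostician's confidence ordering, which compaction
  would distort. If one user's list maps two strings onto the same
  concept, only the best-ranked occurrence counts (no double voting).

## Tie-breaking and numerics

Tied collective scores are ordered by tag priority and then randomized.
Randomization is reproducible: each (case, group, rule) gets a tie seed
derived from the global run seed via blake2b, and the within-ranking
shuffle keys are blake2b(seed, concept id) — never Python's process-
salted `hash`. Scores are accumulated as exact integers scaled by
lcm(1..max rank) (squared for the 1/r² rule), so ties like
1/2 + 1/3 + 1/6 = 1/1 are detected exactly rather than at a floating
tolerance; reported scores are floats of magnitude Σ 1/r.

## Evaluation design

- Exhaustive enumeration of all C(n, k) groups per case is the default
  (1023 groups for n = 10 over k = 1..10); a seeded sampling mode exists
  for larger pools.
- Accuracy is the per-case mean over groups, then the unweighted mean
  over cases, so a case contributes equally regardless of its group
  count. Cases with fewer than k eligible users are skipped for that k,
  not zero-filled.
- Case-level strata (specialty, chief complaint) filter the case set.
  The tenure comparison is within-case: only cases with at least three
  mapped users of every compared tenure level enter, and groups are
  drawn from one tenure level at a time, which avoids confounding by
  self-selection of users into cases.
- Cases whose correct diagnosis cannot be mapped are excluded outright:
  without a verified correct concept, accuracy is undefined.

## Synthetic data: what it emulates, what it does not

The generator stands in for two datasets that cannot be redistributed: a
licensed clinical terminology and a proprietary response dataset. It
emulates the statistical structure the method depends on:

- a multi-parent IS-A DAG (≥ 10% of non-root concepts have ≥ 2 parents)
  with semantic-tagged FSNs and synonym variants — acronym, British
  spelling, plural — plus one planted ambiguous synonym shared by a
  disorder/morphologic-abnormality pair, so the disambiguation path is
  always exercised;
- per-rank response structure: each rank-r slot is the correct concept
  with probability p_r, a direct parent/child near-miss with probability
  q, unmatchable gibberish with probability u, otherwise a plausible
  wrong answer. Defaults: p = (0.45, 0.25, 0.15, 0.10, 0.08), q = 0.15,
  u = 0.13, ten users per case, differential lengths truncated-geometric
  on 1..5 (continuation 0.55). The decreasing p_r encodes that rank-1
  entries are the most accurate — the property that makes rank weighting
  beat equal weighting.
- Wrong answers are drawn from the correct concept's radius-3 graph
  neighborhood rather than uniformly: uniform distractors would almost
  never collide or sit near the correct concept, making aggregation
  trivially easy; neighborhood distractors stress tie-breaking and
  hierarchy credit. Direct parents/children are excluded from the wrong
  pool so the near-miss rate stays exactly q.
- Surface noise (random casing, stray periods, padding) is applied to
  emitted synonyms; normalization must undo all of it.

It does **not** emulate: clinical case content (vignettes, findings),
correlated errors between users, user learning over time, or
heterogeneous per-user skill. Passing tests therefore demonstrate that
the pipeline machinery is correct and that the qualitative
wisdom-of-crowds, rule-ordering and hierarchy-credit effects emerge
under rank-skewed individual skill — not that any particular real-world
accuracy level would be reproduced.

## Problem sizes

The reference sweep uses 200 cases × 10 users with exhaustive group
enumeration (sizes 1..10, two rules, four match modes; ~4×10⁵ group
aggregations, a few seconds on one core). Generator parameter recovery
uses 500 cases (~10⁴ entries), giving 3-standard-error windows of about
±2 percentage points on p₁.

## Known limitations

- The stop-word list, spelling table and singularizer are this package's
  own concrete choices; other reasonable choices would move match rates
  slightly. All three are overridable (files / Normalizer arguments).
- Relaxed matching scans every index key (O(#synonyms) per lookup); it
  is meant for sensitivity analyses, not as the default path.
- Hierarchy credit is depth-1 only; deeper credit would need a
  principled distance decay.
- Tie randomization makes top-k accuracy on heavily tied rankings a
  random variable; fixing the global seed makes whole runs reproducible
  but individual tie outcomes remain arbitrary by design.
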