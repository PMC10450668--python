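# crowddx

Collective intelligence for open-ended medical diagnostics: normalize
free-text diagnoses, link them to concepts in a SNOMED-CT-style
polyhierarchical terminology, aggregate the ranked differentials of many
diagnosticians under rank-weighted scoring rules, and measure how top-k
collective accuracy grows with group size — optionally giving credit for
parent/child near-misses in the hierarchy.

The package is for researchers studying wisdom-of-crowds effects in
diagnostics (and for anyone aggregating ranked free-text answers over an
ontology). Because both licensed terminologies and real response datasets
are typically not redistributable, crowddx ships a synthetic-data module
that generates miniature terminologies and diagnostician cohorts with the
statistical structure real data exhibits, so the whole pipeline is
testable end to end out of the box.

## The method

1. **Normalization.** Each free-text diagnosis is reduced to a set of
   lowercase word tokens: punctuation stripped (hyphens/dashes separate
   tokens), stop words removed, British spellings mapped to US forms,
   plurals singularized. Two strings are compared by the Jaccard
   similarity of their token sets, J(A, B) = |A∩B| / |A∪B|.
2. **Concept mapping.** A diagnosis is linked to a terminology concept
   when its token set exactly matches a synonym's token set (J = 1; a
   relaxed threshold is available). If several concepts match, the
   semantic tag decides: disorder ≻ finding ≻ morphologic abnormality ≻
   organism ≻ the rest. Unmatched diagnoses are discarded; survivors keep
   their original rank.
3. **Aggregation.** For a group of diagnosticians, a diagnosis at rank r
   of a member's differential contributes a weight w(r) — 1/r
   (reciprocal), 1/r² , or 1 (equal weighting) — and weights are summed
   per concept. Concepts are sorted by total score; ties break by
   semantic tag, then by a seeded random permutation.
4. **Evaluation.** For every case and group size k, all C(n, k) unique
   groups are enumerated; accuracy is the fraction of groups whose
   collective ranking contains an accepted concept in its top 1, 2 or 3.
   The accepted set is the correct concept alone, or widened with its
   direct parent and/or child concepts (hierarchy credit). Per-case group
   means are averaged over cases with equal case weights.

## Worked example

The bundled micro-case (three diagnosticians, an obstructive sleep apnea
case) runs in one command:

```sh
crowddx demo --out demo_output
```

```
sleep1  #1  78275009  score=1.500  (disorder)
sleep1  #2  60380001  score=1.333  (disorder)
sleep1  #3  73430006  score=1.000  (disorder)
sleep1  #4  193462001  score=0.500  (disorder)
```

User 1 listed "obstructive sleep apnea" at rank 2 and user 2 listed
"OSA—obstructive sleep apnea" at rank 1; both normalize onto concept
78275009, which therefore scores 1/2 + 1/1 = 1.5 under the reciprocal
rule and tops the collective ranking. "sleep apnea" (73430006) is a
different, broader concept, and one diagnosis ("circadian rhythm sleep
disorder") has no synonym in the micro-terminology and is discarded.

The same flow from Python, plus synthetic cohorts and full sweeps, is in
`examples/` (one short script per capability). A full synthetic sweep:

```sh
crowddx synth cohort --seed 42 --out-cases cases.csv \
    --out-responses responses.csv --out-terminology terminology.json
crowddx simulate --terminology terminology.json --cases cases.csv \
    --responses responses.csv --rules reciprocal --modes exact,exact+both \
    --seed 42 --out simulation
```

which writes a tidy `accuracy.csv` (one row per group size × rule ×
top-k × match mode) and a manifest recording the seed, configuration
hash, and per-stage record counts. On synthetic cohorts, top-3 accuracy
under the reciprocal rule typically climbs from ~0.6 for single
diagnosticians to ~1.0 for groups of ten, equal weighting trails the
reciprocal rules, and hierarchy credit adds a further gain at every
group size.

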