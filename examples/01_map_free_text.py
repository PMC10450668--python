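"""Normalize free-text diagnoses and map them to terminology concepts.

Uses the bundled sleep-apnea micro-terminology.  Different surface forms
("OSA", "O.S.A.", "OSA—obstructive sleep apnea") all land on the same
concept; a string with no synonym in the terminology stays unmatched.
"""

from crowddx import demo_inputs, map_term, normalize

graph, _ = demo_inputs()

for text in [
    "OSA—obstructive sleep apnea",
    "O.S.A.",
    "Obstructive sleep apnea",
    "sleep apnoea",  # British spelling of a *different*, broader concept
    "circadian rhythm sleep disorder",  # not in this terminology
]:
    tokens = sorted(normalize(text).tokens)
    res = map_term(text, graph)
    print(f"{text!r:40} tokens={tokens} -> {res.status}: {res.concept_id}")

# The printed concept id is the terminology identifier the diagnosis was
# linked to; "unmatched" entries would be discarded before aggregation.
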