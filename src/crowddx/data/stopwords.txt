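# Minimal clinical-safe stop-word list: articles, common prepositions,
# conjunctions. Deliberately short — words like "acute", "right", "upper"
# carry clinical meaning and are never removed.
a
an
the
of
in
on
at
to
for
with
by
from
and
or
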