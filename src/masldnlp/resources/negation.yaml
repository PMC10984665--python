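# Trigger-based negation rules. A pre-trigger negates mentions from the
# trigger forward to the nearest scope terminator (or sentence end); a
# post-trigger negates backward to the nearest terminator (or sentence
# start). Scoping never crosses a sentence boundary. Diminutive qualifiers
# are listed only for documentation/tests: they are NOT triggers — under the
# scoring rubric "minimal", "patchy", and "borderline" still count as
# feature presence.
pre_triggers:
  - "no"
  - without
  - "negative for"
  - "absence of"
  - "no evidence of"
  - "no evidence for"
  - "free of"
  - "lacks"
  - "lacking"
  - "not"
  - "rule out"
  - "insufficient for"
  - "no significant"
  - "no definite"
  - "no histologic evidence of"
post_triggers:
  - "is absent"
  - "are absent"
  - "is not seen"
  - "are not seen"
  - "not seen"
  - "not identified"
  - "is not identified"
  - "are not identified"
  - "not present"
  - "is not present"
  - "are not present"
  - "not appreciated"
  - "absent"
scope_terminators:
  - "but"
  - "however"
  - "although"
  - "aside from"
  - "except"
  - ";"
  - ":"
  - "."
diminutives:
  - minimal
  - patchy
  - borderline
  - mild
  - focal
  - rare
  - occasional
  - scattered
  - early
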