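# Default context-trigger lexicon for the rules engine.
#
# Each category lists pre-mention and post-mention triggers. A trigger's
# scope runs `scope_window` tokens in its direction and is cut short by a
# sentence boundary or a scope terminator. Trigger lists must be disjoint
# across categories.
scope_window: 6
negation:
  pre:
    - denies
    - denied
    - denying
    - "no"
    - not
    - without
    - negative for
    - absence of
    - free of
  post:
    - is absent
    - was absent
    - absent
hypothetical:
  pre:
    - may cause
    - might cause
    - can cause
    - could cause
    - risk of
    - watch for
    - return if
    - if
    - in case of
    - should
  post:
    - is possible
not_patient:
  pre:
    - mother
    - father
    - sister
    - brother
    - wife
    - husband
    - son has
    - daughter has
    - grandmother
    - grandfather
    - family history of
    - roommate
  post: []
other:
  pre:
    - handout on
    - pamphlet on
  post:
    - etiquette
    - questionnaire
    - hygiene reviewed
terminators:
  - but
  - however
  - although
  - though
  - except
  - yet
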