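# Default self-report pattern grammar.
#
# Templates are regular-expression fragments with placeholders:
#   {identity}          -> one identity term per surface pattern
#   {person}            -> one person term per surface pattern
#   {person_or_people}  -> person terms plus the collective terms below
# Each (template x term combination) expands to one surface pattern,
# compiled case-insensitively with word-boundary anchors.  Multi-word
# terms match across any whitespace.
#
# Tweet templates require a first-person anchor; profile templates do
# not (profile text is self-descriptive by convention).  The strict
# exclusions are NOT part of the default operating mode; they trade
# recall for precision and are opt-in via mode="strict".

identity_terms:
  - gay
  - bisexual
  - bi
  - homosexual
  - msm
  - men who have sex with men

person_terms:
  - man
  - men
  - guy
  - guys
  - male
  - males
  - dude
  - dudes
  - boy
  - boys

collective_terms:
  - people
  - folks

tweet_templates:
  - id: first_person_is
    pattern: "i\\s*['’]?\\s*a?m\\s+an?\\s+(?:\\w+\\s+){0,2}{identity}\\s+{person}"
  - id: as_a
    pattern: "as\\s+an?\\s+(?:\\w+\\s+){0,2}{identity}\\s+{person}"
  - id: like_me
    pattern: "{identity}\\s+{person_or_people}\\s+like\\s+me"
  - id: being_a
    pattern: "being\\s+an?\\s+(?:\\w+\\s+){0,2}{identity}\\s+{person}"

profile_templates:
  - id: profile_identity_person
    pattern: "{identity}\\s+(?:\\w+\\s+){0,2}{person}"

strict_exclusions:
  third_person_possessives:
    - his
    - her
    - their
  transnb_profile_terms:
    - trans
    - transgender
    - nonbinary
    - non-binary
    - enby
    - genderqueer
    - genderfluid
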