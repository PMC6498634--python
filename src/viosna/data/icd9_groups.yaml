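# Default ICD9-CM chapter ranges for the 13 named diagnostic groups.
# Ranges are inclusive on the numeric code value; earlier entries win, so
# the alcohol/substance ranges take precedence inside the psychoses chapter,
# and the head_face list (below) takes precedence over every numeric range.
# Substitute your own table here if you hold a different grouping.
groups:
  infectious:
    - [1, 139.99]
  alcohol_substance_abuse:
    - [291, 292.99]
    - [303, 305.99]
  psychoses:
    - [290, 299.99]
  other_mental:
    - [300, 302.99]
    - [306, 319.99]
  neurological:
    - [320, 389.99]
  circulatory:
    - [390, 459.99]
  respiratory:
    - [460, 519.99]
  digestive:
    - [520, 579.99]
  genitourinary:
    - [580, 629.99]
  pregnancy_related:
    - [630, 679.99]
  traumatic_musculoskeletal:
    - [710, 739.99]
    - [800, 999.99]
  symptoms_ill_defined:
    - [780, 799.99]
# Diagnoses where head and face were involved, independently of the
# traumatic origin; these win over the traumatic_musculoskeletal ranges.
head_face:
  ranges:
    - [800, 804.99]   # skull fractures
    - [830, 830.99]   # jaw dislocation
    - [870, 873.99]   # open wounds of head
    - [910, 910.99]   # superficial injury of face/head
    - [920, 921.99]   # contusion of face/eye
  codes:
    - "959.01"        # head injury, unspecified
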