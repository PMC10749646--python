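# Default attribute manifest: the 14 vaccine-messaging attributes of the
# case study, in pre-recoding form.  B4 (privacy: watching alone) is
# reverse-recoded during analysis and reported as B4R (company).
attributes:
  - id: A1
    label: video
    group: characteristics
  - id: A2
    label: cartoon
    group: characteristics
  - id: A3
    label: short duration
    group: characteristics
  - id: A4
    label: text
    group: characteristics
  - id: A5
    label: resource information
    group: characteristics
  - id: A6
    label: key message summaries
    group: characteristics
  - id: B1
    label: shareability
    group: distribution
  - id: B2
    label: trusted messenger
    group: distribution
  - id: B3
    label: health center location
    group: distribution
  - id: B4
    label: privacy
    group: distribution
    reverse_recoded: true
  - id: B5
    label: national logo
    group: distribution
  - id: B6
    label: international logo
    group: distribution
  - id: C1
    label: fact-based
    group: content
  - id: C2
    label: story-based
    group: content
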