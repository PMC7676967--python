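# Default 60-item CCMQ configuration.
#
# The judgment thresholds (unbalanced: yes >= 40, tendency >= 30; balanced:
# yes >= 60 with every unbalanced score < 30) and the unbalanced subscale
# sizes (Qi 8, Yang 7, Yin 8, Phlegm 8, Damp-heat 6, Stagnant Blood 7,
# Stagnant Qi 7, Inherited Special 7) follow the published CCMQ standard.
# The concrete item-id blocks are a *reconstruction*: items are assigned in
# contiguous blocks, and the Balanced subscale reuses 3 Qi-deficiency and
# 4 Yang-deficiency items with reversed keying plus one positively keyed
# item of its own (id 59), which reproduces the reference label
# distribution under uniform-random answers, the published
# per-combination question-set sizes, and the published identification
# accuracies. Item 60 (the gender-merged item) is left unscored here.
# VERIFY against the printed instrument before any clinical use; edit this
# file (or pass your own) to correct the mapping - no code changes needed.
items:
- id: 1
  text: ''
  reverse_scored: false
- id: 2
  text: ''
  reverse_scored: false
- id: 3
  text: ''
  reverse_scored: false
- id: 4
  text: ''
  reverse_scored: false
- id: 5
  text: ''
  reverse_scored: false
- id: 6
  text: ''
  reverse_scored: false
- id: 7
  text: ''
  reverse_scored: false
- id: 8
  text: ''
  reverse_scored: false
- id: 9
  text: ''
  reverse_scored: false
- id: 10
  text: ''
  reverse_scored: false
- id: 11
  text: ''
  reverse_scored: false
- id: 12
  text: ''
  reverse_scored: false
- id: 13
  text: ''
  reverse_scored: false
- id: 14
  text: ''
  reverse_scored: false
- id: 15
  text: ''
  reverse_scored: false
- id: 16
  text: ''
  reverse_scored: false
- id: 17
  text: ''
  reverse_scored: false
- id: 18
  text: ''
  reverse_scored: false
- id: 19
  text: ''
  reverse_scored: false
- id: 20
  text: ''
  reverse_scored: false
- id: 21
  text: ''
  reverse_scored: false
- id: 22
  text: ''
  reverse_scored: false
- id: 23
  text: ''
  reverse_scored: false
- id: 24
  text: ''
  reverse_scored: false
- id: 25
  text: ''
  reverse_scored: false
- id: 26
  text: ''
  reverse_scored: false
- id: 27
  text: ''
  reverse_scored: false
- id: 28
  text: ''
  reverse_scored: false
- id: 29
  text: ''
  reverse_scored: false
- id: 30
  text: ''
  reverse_scored: false
- id: 31
  text: ''
  reverse_scored: false
- id: 32
  text: ''
  reverse_scored: false
- id: 33
  text: ''
  reverse_scored: false
- id: 34
  text: ''
  reverse_scored: false
- id: 35
  text: ''
  reverse_scored: false
- id: 36
  text: ''
  reverse_scored: false
- id: 37
  text: ''
  reverse_scored: false
- id: 38
  text: ''
  reverse_scored: false
- id: 39
  text: ''
  reverse_scored: false
- id: 40
  text: ''
  reverse_scored: false
- id: 41
  text: ''
  reverse_scored: false
- id: 42
  text: ''
  reverse_scored: false
- id: 43
  text: ''
  reverse_scored: false
- id: 44
  text: ''
  reverse_scored: false
- id: 45
  text: ''
  reverse_scored: false
- id: 46
  text: ''
  reverse_scored: false
- id: 47
  text: ''
  reverse_scored: false
- id: 48
  text: ''
  reverse_scored: false
- id: 49
  text: ''
  reverse_scored: false
- id: 50
  text: ''
  reverse_scored: false
- id: 51
  text: ''
  reverse_scored: false
- id: 52
  text: ''
  reverse_scored: false
- id: 53
  text: ''
  reverse_scored: false
- id: 54
  text: ''
  reverse_scored: false
- id: 55
  text: ''
  reverse_scored: false
- id: 56
  text: ''
  reverse_scored: false
- id: 57
  text: ''
  reverse_scored: false
- id: 58
  text: ''
  reverse_scored: false
- id: 59
  text: ''
  reverse_scored: false
- id: 60
  text: ''
  reverse_scored: false
subscales:
  Balanced:
    items:
    - 1
    - 2
    - 3
    - 9
    - 10
    - 11
    - 12
    - 59
    reversed:
    - 1
    - 2
    - 3
    - 9
    - 10
    - 11
    - 12
  Qi-deficient:
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
  - 8
  Yang-deficient:
  - 9
  - 10
  - 11
  - 12
  - 13
  - 14
  - 15
  Yin-deficient:
  - 16
  - 17
  - 18
  - 19
  - 20
  - 21
  - 22
  - 23
  Phlegm-dampness:
  - 24
  - 25
  - 26
  - 27
  - 28
  - 29
  - 30
  - 31
  Damp-heat:
  - 32
  - 33
  - 34
  - 35
  - 36
  - 37
  Stagnant Blood:
  - 38
  - 39
  - 40
  - 41
  - 42
  - 43
  - 44
  Stagnant Qi:
  - 45
  - 46
  - 47
  - 48
  - 49
  - 50
  - 51
  Inherited Special:
  - 52
  - 53
  - 54
  - 55
  - 56
  - 57
  - 58
thresholds:
  yes_cutoff: 40.0
  tendency_cutoff: 30.0
  balanced_yes_cutoff: 60.0
  balanced_other_max: 30.0
allow_shared_items: true
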