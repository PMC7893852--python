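# Administrative frailty identification rules for the index year.
# A person is frail if at least one of the three rules fires:
#   1. resident in long-term care or assisted living (any episode overlapping
#      the index year),
#   2. terminally ill (palliative-care coding in the index year),
#   3. at least `efs_min_indices` distinct claims-detectable domains of the
#      modified Edmonton Frail Scale in the index year.
# The published criterion lists defer code specifics to unavailable
# supplemental material; these conservative defaults are editable stand-ins.
terminal_illness:
  icd9: ["V66.7"]
  icd10: ["Z51.5"]
efs_min_indices: 2
efs_domains:
  cognition:
    icd9_prefixes: ["290", "294.8", "331"]
  mood:
    icd9_prefixes: ["296", "300.0", "311"]
  incontinence:
    icd9_prefixes: ["788.3", "625.6"]
  falls_mobility:
    icd9_prefixes: ["V15.88", "781.2"]
  nutrition:
    icd9_prefixes: ["783.2", "263"]
  functional_dependence:
    icd9_prefixes: ["797"]
  social_support:
    icd9_prefixes: ["V60"]
  polypharmacy:
    distinct_atc_threshold: 5
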