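# Rolling-window chronic-condition definitions (eight conditions with
# validated primary-care case definitions).  A person is classified with a
# condition given one hospital diagnosis matching the ICD-10-CA prefixes
# and/or two physician claims matching the ICD-9 prefixes within the rolling
# window.  Depression uses a one-year window and additionally requires
# index-year treatment evidence when the first qualification predates the
# index year.  Code lists are editable stand-ins for the validated
# definitions, which are not reprinted in the source literature.
hypertension:
  icd9_prefixes: ["401", "402", "403", "404", "405"]
  icd10_prefixes: ["I10", "I11", "I12", "I13", "I15"]
  window_days: 730
diabetes:
  icd9_prefixes: ["250"]
  icd10_prefixes: ["E10", "E11", "E13", "E14"]
  window_days: 730
copd:
  icd9_prefixes: ["491", "492", "496"]
  icd10_prefixes: ["J41", "J43", "J44"]
  window_days: 730
osteoarthritis:
  icd9_prefixes: ["715"]
  icd10_prefixes: ["M15", "M16", "M17", "M18", "M19"]
  window_days: 730
dementia:
  icd9_prefixes: ["290"]
  icd10_prefixes: ["F00", "F01", "F02", "F03", "G30"]
  window_days: 730
depression:
  icd9_prefixes: ["296", "311"]
  icd10_prefixes: ["F32", "F33"]
  window_days: 365
  treatment_atc_prefixes: ["N06A"]
epilepsy:
  icd9_prefixes: ["345"]
  icd10_prefixes: ["G40"]
  window_days: 730
parkinsonism:
  icd9_prefixes: ["332"]
  icd10_prefixes: ["G20", "G21"]
  window_days: 730
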