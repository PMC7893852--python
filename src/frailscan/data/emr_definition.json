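{
  "comment": "Default EMR frailty screening definition: reconstruction from the published ingredients (dementia ICD-9 290, vitamin and/or furosemide prescriptions, 'obstruction' free text); the exact learned boolean structure was not published. Override freely.",
  "atoms": {
    "dementia": {"kind": "icd9_prefix", "values": ["290"]},
    "vitamins": {"kind": "atc_prefix", "values": ["A11"]},
    "furosemide": {"kind": "atc_prefix", "values": ["C03CA01"]},
    "obstruction": {"kind": "text_keyword", "values": ["obstruction"]}
  },
  "expression": ["or", "dementia", ["and", "vitamins", "furosemide"], "obstruction"],
  "lookback_years": 6
}
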