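{
  "description": "Published patient counts of the sign-expansion study (development and external validation cohorts); the only patient-level numbers available, used for arithmetic cross-checks.",
  "development": {
    "n_screened": 1059,
    "n_total": 482,
    "n_sign": 212,
    "n_expansion": 307,
    "matched_pairs_text": 158,
    "matched_expansion_sign": 138,
    "matched_expansion_nosign": 71,
    "matched_group_denominator_implied": 152
  },
  "validation": {
    "n_total": 160,
    "n_expansion": 102,
    "matched_pairs": 50,
    "matched_expansion_sign": 44,
    "matched_expansion_nosign": 22
  }
}
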