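{
  "rare_disease": {
    "n_cases": 51,
    "n_dv_initial": 13,
    "n_dv_final": 16,
    "n_vuds_final": 18,
    "dv_inheritance": {
      "de_novo": 8,
      "recessive": 6,
      "dominant": 1,
      "mitochondrial": 1
    }
  },
  "sudden_death": {
    "n_cases": 50,
    "n_dv_initial": 5,
    "n_dv_final": 6,
    "n_vuds_final": 8
  }
}
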