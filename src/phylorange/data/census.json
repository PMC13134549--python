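{
  "records_by_category": {"VU": 430, "EN": 352, "CR": 204},
  "species_by_category": {"CR": 11, "EN": 39, "VU": 19},
  "n_species_modeled": 38,
  "n_species_sequenced": 52
}
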