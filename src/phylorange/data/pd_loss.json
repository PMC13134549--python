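{
  "CMCC-ESM2": {"SSP2-4.5": 34.2, "SSP3-7.0": 41.3},
  "GISS-E2-1-G": {"SSP2-4.5": 22.6, "SSP3-7.0": 24.8}
}
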