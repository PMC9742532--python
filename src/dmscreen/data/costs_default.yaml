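# Published unit costs (CNY) for diabetes screening and confirmatory tests
# in China, and per-diabetic annual potential-complication cost ranges by
# projection horizon (years). Medical prices cover the laboratory test;
# non-medical prices cover e.g. transportation. No discounting is applied.
medical:
  FPG: 9.89
  P2HPG: 23.56
  OGTT: 33.45
  HBA1C: 84.16
nonmedical:
  FPG: 8.3
  P2HPG: 27.5
  OGTT: 27.5
  HBA1C: 8.3
complication_per_dm_year:
  5: [341, 567]
  10: [1302, 2555]
  15: [2802, 5611]
  20: [4428, 8212]
  25: [5258, 9132]
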