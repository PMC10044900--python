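{
  "description": "Reference G(Fe3+) anchors at ~200 s (molecules/100 eV) for comparing simulated scans.",
  "anchors": [
    {"name": "aerated_N1_no_cystamine", "N": 1, "cystamine_M": 0.0, "aerated": true, "value": 15.4, "tolerance": 0.5, "kind": "simulation"},
    {"name": "deaerated_N1_no_cystamine", "N": 1, "cystamine_M": 0.0, "aerated": false, "value": 8.05, "tolerance": 0.3, "kind": "simulation"},
    {"name": "aerated_N1_1e-5M", "N": 1, "cystamine_M": 1e-5, "aerated": true, "value": 14.9, "tolerance": 1.49, "kind": "simulation"},
    {"name": "aerated_N1_1M", "N": 1, "cystamine_M": 1.0, "aerated": true, "value": 4.6, "tolerance": 0.46, "kind": "simulation"},
    {"name": "aerated_N1000_1e-5M", "N": 1000, "cystamine_M": 1e-5, "aerated": true, "value": 9.1, "tolerance": 0.91, "kind": "simulation"},
    {"name": "aerated_N1000_1M", "N": 1000, "cystamine_M": 1.0, "aerated": true, "value": 4.2, "tolerance": 0.42, "kind": "simulation"},
    {"name": "aerated_experimental", "N": 1, "cystamine_M": 0.0, "aerated": true, "value": 15.5, "tolerance": 0.2, "kind": "experiment"},
    {"name": "deaerated_experimental", "N": 1, "cystamine_M": 0.0, "aerated": false, "value": 8.2, "tolerance": 0.3, "kind": "experiment"}
  ]
}
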