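{
  "name": "CXCR4",
  "n_term_side": "EC",
  "chain_range": [1, 281],
  "helices": [
    {"helix_id": 1, "start": 9, "end": 41},
    {"helix_id": 2, "start": 50, "end": 77},
    {"helix_id": 3, "start": 83, "end": 118},
    {"helix_id": 4, "start": 124, "end": 152},
    {"helix_id": 5, "start": 172, "end": 206},
    {"helix_id": 6, "start": 214, "end": 244},
    {"helix_id": 7, "start": 252, "end": 279}
  ]
}
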