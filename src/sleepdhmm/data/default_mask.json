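{
  "state_names": ["Wake", "S1", "S2", "SWS", "REM"],
  "allowed": [
    [1, 1, 0, 0, 0],
    [1, 1, 1, 0, 1],
    [1, 1, 1, 1, 1],
    [0, 0, 1, 1, 0],
    [1, 1, 1, 0, 1]
  ]
}
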