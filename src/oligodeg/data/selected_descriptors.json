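{
  "selected18": [
    "IW1", "IW2", "IW3", "IW4",
    "CW1", "CW2", "CW3", "CW4", "CW5", "CW6", "CW7", "CW8",
    "logP", "PSA", "HSA", "MpKaA", "EMDIF", "EMDIS"
  ],
  "adme_exclusions": ["CACO2", "MetStab", "PB", "VD", "LgBB", "SKIN"]
}
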