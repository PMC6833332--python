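{
  "mP0P1": 0.0259,
  "mPN1PN": 0.0063,
  "mP0G": 0.0018,
  "mPN1G": 0.0037,
  "mP0S": 0.0026,
  "mPN1S": 0.0053,
  "mP0A": 0.0018,
  "mPN1A": 0.0016,
  "mGS": 0.0007,
  "mAD": 0.0010,
  "N": 50,
  "PgH2AX": 0.2385,
  "GKi67": 0.9979,
  "GgH2AX": 0.8237
}
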