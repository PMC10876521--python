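{
  "_comment": "Monoisotopic masses in Da (CODATA/NIST). D is deuterium (2H), tracked as its own symbol so labeled formulas stay integer-exact. 'e' is the electron rest mass, added/removed when forming ions.",
  "C": 12.0,
  "H": 1.0078250319,
  "D": 2.0141017779,
  "O": 15.9949146221,
  "N": 14.0030740052,
  "S": 31.97207069,
  "P": 30.97376151,
  "e": 0.0005485799
}
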