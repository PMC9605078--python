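{
  "version": "1.0",
  "comment": "Fragment contributions (A^2) to topological polar surface area, keyed by atom environment signature: element|aromatic|H-count|single,double,triple heavy-bond counts|formal charge. Sulfur included as polar.",
  "contributions": {
    "N|al|H0|s3d0t0|c0": 3.24,
    "N|al|H0|s1d1t0|c0": 12.36,
    "N|al|H0|s0d0t1|c0": 23.79,
    "N|al|H0|s2d1t0|c0": 11.68,
    "N|al|H1|s2d0t0|c0": 12.03,
    "N|al|H1|s0d1t0|c0": 23.85,
    "N|al|H2|s1d0t0|c0": 26.02,
    "N|ar|H0|a2|c0": 12.89,
    "N|ar|H0|a3|c0": 4.41,
    "N|ar|H0|a2s1|c0": 4.93,
    "N|ar|H1|a2|c0": 15.79,
    "O|al|H0|s2d0t0|c0": 9.23,
    "O|al|H0|s0d1t0|c0": 17.07,
    "O|al|H1|s1d0t0|c0": 20.23,
    "O|al|H0|s1d0t0|c-1": 23.06,
    "O|ar|H0|a2|c0": 13.14,
    "S|al|H0|s2d0t0|c0": 25.30,
    "S|al|H0|s0d1t0|c0": 32.09,
    "S|al|H1|s1d0t0|c0": 38.80,
    "S|ar|H0|a2|c0": 28.24
  }
}
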