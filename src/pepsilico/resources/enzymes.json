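{
  "version": "1.0",
  "rule_sets": {
    "gi-default": {
      "description": "Concurrent gastric/intestinal panel: pepsin + trypsin + chymotrypsin, all-or-none cleavage, no P1' exclusions",
      "enzymes": [
        {"name": "pepsin", "ec": "3.4.23.1", "p1": ["F", "L"], "p1prime_block": []},
        {"name": "trypsin", "ec": "3.4.21.4", "p1": ["K", "R"], "p1prime_block": []},
        {"name": "chymotrypsin", "ec": "3.4.21.1", "p1": ["F", "W", "Y", "M", "L"], "p1prime_block": []}
      ]
    }
  }
}
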