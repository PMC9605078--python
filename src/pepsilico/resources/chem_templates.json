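{
  "version": "1.0",
  "comment": "Side-chain SMILES branches attached at the alpha carbon; proline is handled as a backbone ring closure; arginine guanidine is drawn neutral (one =NH).",
  "side_chains": {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "G": "",
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "P": null,
    "S": "CO",
    "T": "C(O)C",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C"
  },
  "references": {
    "captopril": {
      "smiles": "CC(CS)C(=O)N1CCCC1C(=O)O",
      "description": "ACE-inhibitory drug benchmark: (S)-proline amide of 3-mercapto-2-methylpropanoate; thiol + tertiary amide + carboxylic acid"
    }
  }
}
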