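{
  "version": "1.0",
  "water_average_mass": 18.02,
  "water_monoisotopic_mass": 18.010565,
  "residues": {
    "A": {"name": "Alanine",       "average_mass": 71.08,  "monoisotopic_mass": 71.03711,  "charge_class": "neutral"},
    "R": {"name": "Arginine",      "average_mass": 156.19, "monoisotopic_mass": 156.10111, "charge_class": "basic"},
    "N": {"name": "Asparagine",    "average_mass": 114.10, "monoisotopic_mass": 114.04293, "charge_class": "neutral"},
    "D": {"name": "Aspartic acid", "average_mass": 115.09, "monoisotopic_mass": 115.02694, "charge_class": "acidic"},
    "C": {"name": "Cysteine",      "average_mass": 103.14, "monoisotopic_mass": 103.00919, "charge_class": "neutral"},
    "E": {"name": "Glutamic acid", "average_mass": 129.12, "monoisotopic_mass": 129.04259, "charge_class": "acidic"},
    "Q": {"name": "Glutamine",     "average_mass": 128.13, "monoisotopic_mass": 128.05858, "charge_class": "neutral"},
    "G": {"name": "Glycine",       "average_mass": 57.05,  "monoisotopic_mass": 57.02146,  "charge_class": "neutral"},
    "H": {"name": "Histidine",     "average_mass": 137.14, "monoisotopic_mass": 137.05891, "charge_class": "neutral"},
    "I": {"name": "Isoleucine",    "average_mass": 113.16, "monoisotopic_mass": 113.08406, "charge_class": "neutral"},
    "L": {"name": "Leucine",       "average_mass": 113.16, "monoisotopic_mass": 113.08406, "charge_class": "neutral"},
    "K": {"name": "Lysine",        "average_mass": 128.17, "monoisotopic_mass": 128.09496, "charge_class": "basic"},
    "M": {"name": "Methionine",    "average_mass": 131.19, "monoisotopic_mass": 131.04049, "charge_class": "neutral"},
    "F": {"name": "Phenylalanine", "average_mass": 147.18, "monoisotopic_mass": 147.06841, "charge_class": "neutral"},
    "P": {"name": "Proline",       "average_mass": 97.12,  "monoisotopic_mass": 97.05276,  "charge_class": "neutral"},
    "S": {"name": "Serine",        "average_mass": 87.08,  "monoisotopic_mass": 87.03203,  "charge_class": "neutral"},
    "T": {"name": "Threonine",     "average_mass": 101.10, "monoisotopic_mass": 101.04768, "charge_class": "neutral"},
    "W": {"name": "Tryptophan",    "average_mass": 186.21, "monoisotopic_mass": 186.07931, "charge_class": "neutral"},
    "Y": {"name": "Tyrosine",      "average_mass": 163.18, "monoisotopic_mass": 163.06333, "charge_class": "neutral"},
    "V": {"name": "Valine",        "average_mass": 99.13,  "monoisotopic_mass": 99.06841,  "charge_class": "neutral"}
  },
  "scales": {
    "hopp-woods": {
      "kind": "hydrophilicity",
      "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "E": 3.0, "Q": 0.2,
      "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
      "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5
    },
    "eisenberg-consensus": {
      "kind": "hydrophobicity",
      "A": 0.25, "R": -1.76, "N": -0.64, "D": -0.72, "C": 0.04, "E": -0.62, "Q": -0.69,
      "G": 0.16, "H": -0.40, "I": 0.73, "L": 0.53, "K": -1.10, "M": 0.26, "F": 0.61,
      "P": -0.07, "S": -0.26, "T": -0.18, "W": 0.37, "Y": 0.02, "V": 0.54
    },
    "kyte-doolittle": {
      "kind": "hydrophobicity",
      "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "E": -3.5, "Q": -3.5,
      "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
      "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
    }
  },
  "pka_sets": {
    "sillero": {
      "n_terminus": 8.2, "c_terminus": 3.2,
      "side_chains": {"D": 4.0, "E": 4.5, "H": 6.4, "C": 9.0, "Y": 10.0, "K": 10.4, "R": 12.0}
    },
    "emboss": {
      "n_terminus": 8.6, "c_terminus": 3.6,
      "side_chains": {"D": 3.9, "E": 4.1, "H": 6.5, "C": 8.5, "Y": 10.1, "K": 10.8, "R": 12.5}
    }
  }
}
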