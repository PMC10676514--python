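{
  "modified_base": {
    "name": "Purine (nebularine)",
    "sources": [
      "Jolley EA, Znosko BM (2017) The loss of a hydrogen bond: thermodynamic contributions of a non-standard nucleotide. Nucleic Acids Res 45:1479-1487. doi:10.1093/nar/gkw830"
    ],
    "unmodified": "A",
    "fallback": "A",
    "one_letter_code": "9",
    "pairing_partners": ["U"],
    "stacking_energies": {
      "A9UU": 0.43,
      "C9GU": -0.76,
      "G9CU": -1.1,
      "U9AU": 0.33,
      "9AUU": -0.68,
      "9CUG": -1.98,
      "9GUC": -1.88,
      "9UUA": -0.32
    },
    "stacking_enthalpies": {
      "A9UU": -14.0,
      "C9GU": -12.4,
      "G9CU": -14.2,
      "U9AU": -8.7,
      "9AUU": -10.4,
      "9CUG": -15.7,
      "9GUC": -14.5,
      "9UUA": -11.9
    },
    "terminal_energies": {"9U": 0.86, "U9": 0.86},
    "terminal_enthalpies": {"9U": 2.3, "U9": 2.3}
  }
}
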