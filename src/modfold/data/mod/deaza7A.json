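{
  "modified_base": {
    "name": "7-deaza-adenosine (7DA)",
    "sources": [
      "Richardson KE, Znosko BM (2016) Nearest-neighbor parameters for 7-deaza-adenosine-uridine base pairs in RNA duplexes. RNA 22:934-942. doi:10.1261/rna.055277.115"
    ],
    "unmodified": "A",
    "fallback": "A",
    "one_letter_code": "7",
    "pairing_partners": ["U"],
    "stacking_energies": {
      "A7UU": -0.59,
      "C7GU": -1.81,
      "G7CU": -1.66,
      "U7AU": -1.07,
      "7AUU": -0.68,
      "7CUG": -2.1,
      "7GUC": -1.98,
      "7UUA": -1.46
    },
    "stacking_enthalpies": {
      "A7UU": -8.4,
      "C7GU": -11.8,
      "G7CU": -10.8,
      "U7AU": -9.4,
      "7AUU": -9.9,
      "7CUG": -14.8,
      "7GUC": -15.1,
      "7UUA": -13.9
    },
    "terminal_energies": {"7U": 0.31, "U7": 0.31},
    "terminal_enthalpies": {"7U": 9.3, "U7": 9.3}
  }
}
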