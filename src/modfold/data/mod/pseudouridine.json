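{
  "modified_base": {
    "name": "Pseudouridine",
    "sources": [
      "Hudson GA, Bloomingdale RJ, Znosko BM (2013) Thermodynamic contribution and nearest-neighbor parameters of pseudouridine-adenosine base pairs in oligoribonucleotides. RNA 19:1474-1482. doi:10.1261/rna.039610.113"
    ],
    "unmodified": "U",
    "fallback": "U",
    "one_letter_code": "P",
    "pairing_partners": ["A"],
    "stacking_energies": {
      "APUA": -2.8,
      "CPGA": -2.77,
      "GPCA": -3.29,
      "UPAA": -1.62,
      "PAAU": -2.1,
      "PCAG": -2.49,
      "PGAC": -2.2,
      "PUAA": -2.74
    },
    "stacking_enthalpies": {
      "APUA": -22.08,
      "CPGA": -16.23,
      "GPCA": -24.07,
      "UPAA": -20.81,
      "PAAU": -12.47,
      "PCAG": -17.29,
      "PGAC": -11.19,
      "PUAA": -26.94
    },
    "terminal_energies": {"PA": 0.31, "AP": 0.31},
    "terminal_enthalpies": {"PA": -2.04, "AP": -2.04}
  }
}
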