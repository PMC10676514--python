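{
  "modified_base": {
    "name": "Dihydrouridine",
    "sources": [
      "Monte-Carlo simulation estimates of dihydrouridine-adenosine nearest-neighbor parameters (no direct melting measurements exist)",
      "Dalluge JJ et al. (1996) Conformational flexibility in RNA: the role of dihydrouridine. Nucleic Acids Res 24:1073-1079"
    ],
    "unmodified": "U",
    "fallback": "U",
    "one_letter_code": "D",
    "pairing_partners": ["A"],
    "stacking_energies": {
      "ADUA": -0.62,
      "CDGA": -2.03,
      "GDCA": -1.0,
      "UDAA": -0.54,
      "DAAU": -0.49,
      "DCAG": -1.28,
      "DGAC": -0.71,
      "DUAA": -0.61
    },
    "stacking_enthalpies": {
      "ADUA": -7.6,
      "CDGA": -9.8,
      "GDCA": -7.38,
      "UDAA": -8.07,
      "DAAU": -9.44,
      "DCAG": -10.55,
      "DGAC": -9.1,
      "DUAA": -8.57
    },
    "terminal_energies": {"AD": 0.26, "DA": 0.26},
    "terminal_enthalpies": {"AD": 0.44, "DA": 0.44}
  }
}
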