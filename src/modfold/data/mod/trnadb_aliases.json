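{
  "\"": {"name": "1-methyladenosine (m1A)", "fallback": "A", "unpaired": true},
  "R": {"name": "N2,N2-dimethylguanosine (m22G)", "fallback": "G", "unpaired": true},
  "L": {"name": "N2-methylguanosine (m2G)", "fallback": "G"},
  "B": {"name": "2'-O-methylcytidine (Cm)", "fallback": "C"},
  "#": {"name": "2'-O-methylguanosine (Gm)", "fallback": "G"},
  "W": {"name": "wybutosine / o2yW", "fallback": "A"},
  "7": {"name": "7-methylguanosine (m7G)", "fallback": "G"},
  "?": {"name": "5-methylcytidine (m5C)", "fallback": "C"},
  "T": {"name": "5-methyluridine (m5U)", "fallback": "U"}
}
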