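{
  "H": 1.2,
  "C": 1.7,
  "N": 1.55,
  "O": 1.52,
  "S": 1.8,
  "P": 1.8,
  "F": 1.47,
  "CL": 1.75,
  "BR": 1.85,
  "I": 1.98,
  "SE": 1.9,
  "B": 1.92,
  "ZN": 1.39,
  "MG": 1.73,
  "CA": 2.31,
  "MN": 1.97,
  "FE": 1.94,
  "NA": 2.27,
  "K": 2.75,
  "CU": 1.4,
  "NI": 1.63,
  "CO": 1.53,
  "CD": 1.58,
  "HG": 1.55
}
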