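{
  "backbone": {
    "N": "donor",
    "O": "acceptor",
    "OXT": "anion"
  },
  "residues": {
    "ALA": {"singles": {"CB": ["hydrophobe"]}},
    "ARG": {"groups": [{"atoms": ["NE", "NH1", "NH2"], "type": "cation"}]},
    "ASN": {"singles": {"OD1": ["acceptor"], "ND2": ["donor"]}},
    "ASP": {"groups": [{"atoms": ["OD1", "OD2"], "type": "anion"}]},
    "CYS": {"singles": {"SG": ["donor"]}},
    "GLN": {"singles": {"OE1": ["acceptor"], "NE2": ["donor"]}},
    "GLU": {"groups": [{"atoms": ["OE1", "OE2"], "type": "anion"}]},
    "GLY": {},
    "HIS": {"singles": {"ND1": ["acceptor"], "NE2": ["acceptor"]}},
    "ILE": {"singles": {"CB": ["hydrophobe"], "CG1": ["hydrophobe"], "CG2": ["hydrophobe"], "CD1": ["hydrophobe"]}},
    "LEU": {"singles": {"CB": ["hydrophobe"], "CG": ["hydrophobe"], "CD1": ["hydrophobe"], "CD2": ["hydrophobe"]}},
    "LYS": {"singles": {"NZ": ["cation"]}},
    "MET": {"singles": {"CB": ["hydrophobe"], "CG": ["hydrophobe"], "CE": ["hydrophobe"]}},
    "PHE": {"singles": {"CB": ["hydrophobe"]},
            "groups": [{"atoms": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], "type": "hydrophobe"}]},
    "PRO": {"singles": {"CB": ["hydrophobe"], "CG": ["hydrophobe"], "CD": ["hydrophobe"]}},
    "SER": {"singles": {"OG": ["donor", "acceptor"]}},
    "THR": {"singles": {"OG1": ["donor", "acceptor"]}},
    "TRP": {"singles": {"CB": ["hydrophobe"], "NE1": ["donor"]},
            "groups": [{"atoms": ["CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"], "type": "hydrophobe"}]},
    "TYR": {"singles": {"OH": ["donor", "acceptor"]}},
    "VAL": {"singles": {"CB": ["hydrophobe"], "CG1": ["hydrophobe"], "CG2": ["hydrophobe"]}}
  },
  "his_cation_group": {"atoms": ["ND1", "NE2"], "type": "cation"},
  "element_fallback": {"N": "donor", "O": "acceptor", "C": "hydrophobe", "S": "hydrophobe"}
}
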