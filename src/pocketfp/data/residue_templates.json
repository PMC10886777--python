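{
  "_comment": "Interaction-site templates for the 20 standard amino acids. Keys per residue: donors = donor-capable heavy atoms (hydrogens resolved by proximity in frame 0); acceptors = acceptor atom -> bonded heavy neighbours; rings = aromatic ring atom-name lists; cations/anions = [atom-name list, formal charge]; hydrophobes = apolar side-chain carbon/sulfur atoms. Backbone sites (N donor except PRO, O acceptor with neighbour C) are added programmatically. HIS is typed neutral: pi ring plus ND1/NE2 donor-and-acceptor, no protonation inference.",
  "backbone": {
    "donors": ["N"],
    "acceptors": {"O": ["C"], "OXT": ["C"]}
  },
  "residues": {
    "ALA": {"hydrophobes": ["CB"]},
    "ARG": {"donors": ["NE", "NH1", "NH2"],
            "cations": [[["NH1", "NH2", "NE", "CZ"], 1]]},
    "ASN": {"donors": ["ND2"], "acceptors": {"OD1": ["CG"]}},
    "ASP": {"acceptors": {"OD1": ["CG"], "OD2": ["CG"]},
            "anions": [[["OD1", "OD2"], -1]]},
    "CYS": {"donors": ["SG"], "acceptors": {"SG": ["CB"]},
            "hydrophobes": ["CB", "SG"]},
    "GLN": {"donors": ["NE2"], "acceptors": {"OE1": ["CD"]}},
    "GLU": {"acceptors": {"OE1": ["CD"], "OE2": ["CD"]},
            "anions": [[["OE1", "OE2"], -1]]},
    "GLY": {},
    "HIS": {"donors": ["ND1", "NE2"],
            "acceptors": {"ND1": ["CG", "CE1"], "NE2": ["CD2", "CE1"]},
            "rings": [["CG", "ND1", "CD2", "CE1", "NE2"]]},
    "ILE": {"hydrophobes": ["CB", "CG1", "CG2", "CD1"]},
    "LEU": {"hydrophobes": ["CB", "CG", "CD1", "CD2"]},
    "LYS": {"donors": ["NZ"], "cations": [[["NZ"], 1]]},
    "MET": {"hydrophobes": ["CB", "CG", "SD", "CE"]},
    "PHE": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
            "hydrophobes": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "PRO": {"no_backbone_donor": true,
            "hydrophobes": ["CB", "CG", "CD"]},
    "SER": {"donors": ["OG"], "acceptors": {"OG": ["CB"]}},
    "THR": {"donors": ["OG1"], "acceptors": {"OG1": ["CB"]}},
    "TRP": {"donors": ["NE1"],
            "rings": [["CG", "CD1", "NE1", "CE2", "CD2"],
                      ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
            "hydrophobes": ["CB", "CG", "CD1", "CD2", "CE2", "CE3",
                             "CZ2", "CZ3", "CH2"]},
    "TYR": {"donors": ["OH"], "acceptors": {"OH": ["CZ"]},
            "rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
            "hydrophobes": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "VAL": {"hydrophobes": ["CB", "CG1", "CG2"]}
  }
}
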