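{
 "description": "Canonical residue table: pH-7 side-chain charges, named per-residue scales (Kyte-Doolittle hydropathy, Chou-Fasman beta propensity, aromaticity), and reduced-representation side-chain pseudo-atom typing.",
 "version": 1,
 "residues": {
  "A": {
   "three_letter": "ALA",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 1.8,
    "beta_propensity": 0.83,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "C",
    "radius": 1.6,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "C": {
   "three_letter": "CYS",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 2.5,
    "beta_propensity": 1.19,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "S",
    "radius": 1.8,
    "hydrophobic": false,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "D": {
   "three_letter": "ASP",
   "side_chain_charge": -1,
   "scales": {
    "hydrophobicity": -3.5,
    "beta_propensity": 0.54,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "O",
    "radius": 1.9,
    "hydrophobic": false,
    "h_bond_donor": false,
    "h_bond_acceptor": true,
    "aromatic": false,
    "charged": true,
    "formal_charge": -1
   }
  },
  "E": {
   "three_letter": "GLU",
   "side_chain_charge": -1,
   "scales": {
    "hydrophobicity": -3.5,
    "beta_propensity": 0.37,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "O",
    "radius": 2.0,
    "hydrophobic": false,
    "h_bond_donor": false,
    "h_bond_acceptor": true,
    "aromatic": false,
    "charged": true,
    "formal_charge": -1
   }
  },
  "F": {
   "three_letter": "PHE",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 2.8,
    "beta_propensity": 1.38,
    "aromaticity": 1.0
   },
   "side_chain": {
    "element": "C",
    "radius": 2.2,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": true,
    "charged": false,
    "formal_charge": 0
   }
  },
  "G": {
   "three_letter": "GLY",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -0.4,
    "beta_propensity": 0.75,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "C",
    "radius": 1.2,
    "hydrophobic": false,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "H": {
   "three_letter": "HIS",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -3.2,
    "beta_propensity": 0.87,
    "aromaticity": 1.0
   },
   "side_chain": {
    "element": "N",
    "radius": 2.0,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": true,
    "aromatic": true,
    "charged": false,
    "formal_charge": 0
   }
  },
  "I": {
   "three_letter": "ILE",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 4.5,
    "beta_propensity": 1.6,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "C",
    "radius": 2.0,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "K": {
   "three_letter": "LYS",
   "side_chain_charge": 1,
   "scales": {
    "hydrophobicity": -3.9,
    "beta_propensity": 0.74,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "N",
    "radius": 2.1,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": true,
    "formal_charge": 1
   }
  },
  "L": {
   "three_letter": "LEU",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 3.8,
    "beta_propensity": 1.3,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "C",
    "radius": 2.0,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "M": {
   "three_letter": "MET",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 1.9,
    "beta_propensity": 1.05,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "S",
    "radius": 2.0,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "N": {
   "three_letter": "ASN",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -3.5,
    "beta_propensity": 0.89,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "N",
    "radius": 1.9,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": true,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "P": {
   "three_letter": "PRO",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -1.6,
    "beta_propensity": 0.55,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "C",
    "radius": 1.9,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "Q": {
   "three_letter": "GLN",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -3.5,
    "beta_propensity": 1.1,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "N",
    "radius": 2.0,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": true,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "R": {
   "three_letter": "ARG",
   "side_chain_charge": 1,
   "scales": {
    "hydrophobicity": -4.5,
    "beta_propensity": 0.93,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "N",
    "radius": 2.2,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": true,
    "formal_charge": 1
   }
  },
  "S": {
   "three_letter": "SER",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -0.8,
    "beta_propensity": 0.75,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "O",
    "radius": 1.7,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": true,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "T": {
   "three_letter": "THR",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -0.7,
    "beta_propensity": 1.19,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "O",
    "radius": 1.8,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": true,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "V": {
   "three_letter": "VAL",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": 4.2,
    "beta_propensity": 1.7,
    "aromaticity": 0.0
   },
   "side_chain": {
    "element": "C",
    "radius": 1.9,
    "hydrophobic": true,
    "h_bond_donor": false,
    "h_bond_acceptor": false,
    "aromatic": false,
    "charged": false,
    "formal_charge": 0
   }
  },
  "W": {
   "three_letter": "TRP",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -0.9,
    "beta_propensity": 1.37,
    "aromaticity": 1.0
   },
   "side_chain": {
    "element": "N",
    "radius": 2.4,
    "hydrophobic": true,
    "h_bond_donor": true,
    "h_bond_acceptor": false,
    "aromatic": true,
    "charged": false,
    "formal_charge": 0
   }
  },
  "Y": {
   "three_letter": "TYR",
   "side_chain_charge": 0,
   "scales": {
    "hydrophobicity": -1.3,
    "beta_propensity": 1.47,
    "aromaticity": 1.0
   },
   "side_chain": {
    "element": "O",
    "radius": 2.2,
    "hydrophobic": false,
    "h_bond_donor": true,
    "h_bond_acceptor": true,
    "aromatic": true,
    "charged": false,
    "formal_charge": 0
   }
  }
 }
}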