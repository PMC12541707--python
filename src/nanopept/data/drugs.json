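{
 "description": "Built-in drug definitions. Coordinates are generated at load time by seeded distance-geometry embedding of the SMILES; formal charges are the pH-7 assignment consistent with the designed charge-neutral ratios. The net-charge assignment is an inference from the neutrality arithmetic, not an experimental pKa calculation.",
 "version": 1,
 "embed_seed": 20260926,
 "drugs": {
  "EPI": {
   "smiles": "CC1OC(OC2CC(O)(C(=O)CO)Cc3cc4C(=O)c5cccc(OC)c5C(=O)c4c(O)c23)CC([NH3+])C1O",
   "net_charge": 1,
   "full_name": "epirubicin",
   "note": "anthracycline; protonated daunosamine amine gives +1; constitutional graph shared with doxorubicin (4'-epimer)"
  },
  "DOX": {
   "smiles": "CC1OC(OC2CC(O)(C(=O)CO)Cc3cc4C(=O)c5cccc(OC)c5C(=O)c4c(O)c23)CC([NH3+])C1O",
   "net_charge": 1,
   "full_name": "doxorubicin",
   "note": "anthracycline; protonated daunosamine amine gives +1"
  },
  "MTX": {
   "smiles": "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)NC(CCC(=O)[O-])C(=O)[O-]",
   "net_charge": -2,
   "full_name": "methotrexate",
   "note": "both glutamate carboxylates deprotonated at pH 7"
  },
  "MIT": {
   "smiles": "CO[C]12[CH](COC(N)=O)C3=C(C(=O)C(C)=C(N)C3=O)N1C[CH]1N[CH]12",
   "net_charge": 0,
   "full_name": "mitomycin C",
   "note": "neutral at pH 7"
  },
  "5FU": {
   "smiles": "O=c1[nH]cc(F)c(=O)[nH]1",
   "net_charge": 0,
   "full_name": "5-fluorouracil",
   "note": "neutral at pH 7"
  },
  "CPT": {
   "smiles": "CCC1(O)C(=O)OCc2c1cc1n(c2=O)Cc2cc3ccccc3nc21",
   "net_charge": 0,
   "full_name": "camptothecin",
   "note": "lactone form, neutral"
  },
  "CP": {
   "smiles": "O=P1(N(CCCl)CCCl)NCCCO1",
   "net_charge": 0,
   "full_name": "cyclophosphamide",
   "note": "neutral at pH 7"
  },
  "OrangeG": {
   "smiles": "Cc1ccc(cc1)N=Nc1c(O)ccc2cc(cc(c12)S(=O)(=O)[O-])S(=O)(=O)[O-]",
   "net_charge": -2,
   "full_name": "Orange G",
   "note": "azo dye used as the reference pose template; both sulfonates ionized"
  }
 }
}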