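{
  "schema_version": "1.0",
  "comment": [
    "Malonyl-CoA analog extender units selected by AT domains. Each entry",
    "gives the alpha-substituent R' installed on the new alpha carbon during",
    "decarboxylative condensation, as a SMILES branch fragment; the empty",
    "string means hydrogen (malonyl-CoA itself). The set covers the named",
    "analogs observed in natural and engineered type I PKSs (see Chan et al.,",
    "Nat. Prod. Rep. 26:90-114, 2009; Ray & Moore, Nat. Prod. Rep.",
    "33:150-161, 2016). 'U' marks an AT whose specificity prediction failed;",
    "the simulator substitutes malonyl and flags the intermediate as",
    "low-confidence."
  ],
  "extenders": {
    "malonyl": "",
    "methylmalonyl": "C",
    "ethylmalonyl": "CC",
    "propylmalonyl": "CCC",
    "isopropylmalonyl": "C(C)C",
    "butylmalonyl": "CCCC",
    "isobutylmalonyl": "CC(C)C",
    "pentylmalonyl": "CCCCC",
    "hexylmalonyl": "CCCCCC",
    "heptylmalonyl": "CCCCCCC",
    "octylmalonyl": "CCCCCCCC",
    "allylmalonyl": "CC=C",
    "propargylmalonyl": "CC#C",
    "crotylmalonyl": "CC=CC",
    "benzylmalonyl": "Cc1ccccc1",
    "hydroxymalonyl": "O",
    "methoxymalonyl": "OC",
    "aminomalonyl": "N",
    "chloroethylmalonyl": "CCCl",
    "azidoethylmalonyl": "CCN=[N+]=[N-]",
    "hydroxyethylmalonyl": "CCO",
    "cyclopropylmalonyl": "C1CC1"
  }
}
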