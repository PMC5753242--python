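{
  "schema_version": "1.0",
  "comment": [
    "Loading-module starter units. acyl_smiles is the starter acyl group",
    "already tethered as its minimal thioester surrogate (acyl thioacid,",
    "C(=O)S with an implicit S-H standing in for the phosphopantetheine",
    "arm). Storing the tethered form removes any ambiguity about which",
    "carboxylate of a polyacid starter is loaded."
  ],
  "starters": {
    "acetyl": "CC(S)=O",
    "propionyl": "CCC(S)=O",
    "butyryl": "CCCC(S)=O",
    "isobutyryl": "CC(C)C(S)=O",
    "2-methylbutyryl": "CC[C@H](C)C(S)=O",
    "isovaleryl": "CC(C)CC(S)=O",
    "benzoyl": "O=C(S)c1ccccc1",
    "cyclohexanecarbonyl": "O=C(S)C1CCCCC1",
    "3-amino-5-hydroxybenzoyl": "Nc1cc(O)cc(C(S)=O)c1",
    "succinyl": "OC(=O)CCC(S)=O",
    "malonamyl": "NC(=O)CC(S)=O",
    "trans-1,2-cyclopentanedicarboxylic acid": "OC(=O)[C@H]1CCC[C@@H]1C(S)=O",
    "lactyl": "C[C@H](O)C(S)=O",
    "glycolyl": "OCC(S)=O"
  }
}
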