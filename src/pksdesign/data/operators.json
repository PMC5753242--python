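{
  "schema_version": "1.0",
  "comment": [
    "Reaction operators applied by the simulation engine, stored as data so",
    "the chemistry is auditable and editable without code changes. All",
    "operators are anchored at the thioester cap ([SX2;H1]C(=O)...) so they",
    "act only on the alpha/beta positions of the growing chain, never on",
    "carbonyls deeper in a poly-beta-ketone. Stereochemical outcomes (KR CIP",
    "targets, DH double-bond geometry, ER alpha configuration) are applied by",
    "the engine as a post-step on the matched atoms, because atom-map parity",
    "in a SMARTS product cannot pin a CIP descriptor across substituent",
    "classes.",
    "extend_template: '{rprime}' is replaced by the extender unit's",
    "alpha-substituent branch, e.g. '(C)' for methylmalonyl or '' for",
    "malonyl."
  ],
  "operators": {
    "extend_template": "[SX2;H1:1]-[C:2]=[O:3]>>[S:1]C(=O)C{rprime}[C:2]=[O:3]",
    "kr_reduce": "[SX2;H1:1][C:2](=[O:3])[C:4][C:5](=[O:6])[#6:7]>>[S:1][C:2](=[O:3])[C:4][C:5]([OH:6])[#6:7]",
    "dehydrate": "[SX2;H1:1][C:2](=[O:3])[C;!H0:4][C:5]([OX2H1])[#6:6]>>[S:1][C:2](=[O:3])[C:4]=[C:5][#6:6]",
    "enoyl_reduce": "[SX2;H1:1][C:2](=[O:3])[C:4]=[C:5]>>[S:1][C:2](=[O:3])[C:4][C:5]",
    "c_methylate": "[SX2;H1:1][C:2](=[O:3])[C;!H0:4]>>[S:1][C:2](=[O:3])[C:4]C",
    "o_methylate": "[SX2;H1:1][C:2](=[O:3])[C:4][C:5][OX2H1:6]>>[S:1][C:2](=[O:3])[C:4][C:5][O:6]C",
    "hydrolyze": "[SX2;H1:1][C:2]=[O:3]>>O[C:2]=[O:3]"
  }
}
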