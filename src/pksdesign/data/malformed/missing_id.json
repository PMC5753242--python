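{
  "$schema_version": "1.0",
  "name": "cluster without an id",
  "subunits": [
    {"name": "S1", "sequence": "MKT",
     "modules": [{"index": 0, "is_loading": true, "domains": [
       {"kind": "AT_L", "substrate_specificity": "acetyl"},
       {"kind": "ACP"}]}]}
  ]
}
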