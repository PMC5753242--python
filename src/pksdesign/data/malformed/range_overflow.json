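{
  "$schema_version": "1.0",
  "id": "range_overflow",
  "name": "residue range beyond sequence end",
  "subunits": [
    {"name": "S1", "sequence": "MKTAYIAKQR",
     "modules": [{"index": 0, "is_loading": true, "domains": [
       {"kind": "AT_L", "substrate_specificity": "acetyl",
        "residue_range": [1, 50]},
       {"kind": "ACP", "residue_range": [51, 60]}]}]}
  ]
}
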