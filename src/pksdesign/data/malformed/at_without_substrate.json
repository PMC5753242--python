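{
  "$schema_version": "1.0",
  "id": "at_without_substrate",
  "name": "AT domain with no substrate annotation",
  "subunits": [
    {"name": "S1", "sequence": "",
     "modules": [{"index": 0, "is_loading": true, "domains": [
       {"kind": "AT_L", "substrate_specificity": "acetyl"},
       {"kind": "ACP"}]}]},
    {"name": "S2", "sequence": "",
     "modules": [{"index": 1, "domains": [
       {"kind": "KS"}, {"kind": "AT"}, {"kind": "ACP"}]}]}
  ]
}
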