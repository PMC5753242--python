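{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "pksdesign/cluster.schema.json",
  "title": "PKS cluster interchange document",
  "description": "Hierarchical description of a type I modular PKS: cluster -> subunits -> modules -> domains. The hierarchy is the conventional one for assembly-line PKSs; field names beyond that hierarchy (activity flags, substrate names, KR types, TE modes, residue coordinates) are this package's own, versioned definition. Residue coordinates are 1-based inclusive, the standard protein feature convention. Validation is enforced in code (pksdesign.model); this file is the normative documentation of the format.",
  "type": "object",
  "required": ["$schema_version", "id", "name", "subunits"],
  "properties": {
    "$schema_version": {"const": "1.0"},
    "id": {"type": "string", "minLength": 1},
    "name": {"type": "string"},
    "known_product": {"type": ["string", "null"], "description": "SMILES of the characterized final product, if any"},
    "truncated": {"type": "boolean", "default": false},
    "provenance": {"type": "object", "description": "free-form source metadata, e.g. database accessions"},
    "subunits": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "modules"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "sequence": {"type": "string", "pattern": "^[ACDEFGHIKLMNPQRSTVWYX]*$"},
          "modules": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["index", "domains"],
              "properties": {
                "index": {"type": "integer", "minimum": 0, "description": "0-based position in the cluster catalytic order; 0 is the loading module"},
                "is_loading": {"type": "boolean", "default": false},
                "iterations": {"type": "integer", "minimum": 1, "default": 1, "description": ">1 encodes an iterating module"},
                "domains": {
                  "type": "array",
                  "minItems": 1,
                  "items": {
                    "type": "object",
                    "required": ["kind"],
                    "properties": {
                      "kind": {"enum": ["AT_L", "KS", "AT", "KR", "DH", "ER", "cMT", "oMT", "ACP", "TE"]},
                      "active": {"type": "boolean", "default": true},
                      "substrate_specificity": {"type": "string", "description": "starter (AT_L) or extender (AT) name; required for and restricted to AT/AT_L"},
                      "kr_type": {"enum": ["A1", "A2", "B1", "B2", "C1", "C2", "U"], "description": "required for and restricted to KR"},
                      "te_mode": {"enum": ["hydrolysis", "cyclization"], "description": "required for and restricted to TE"},
                      "cyclization_site": {"type": "integer", "minimum": 1, "description": "1-based ketide-unit index bearing the attacking hydroxyl (TE cyclization only)"},
                      "residue_range": {
                        "type": ["array", "null"],
                        "items": {"type": "integer", "minimum": 1},
                        "minItems": 2, "maxItems": 2,
                        "description": "[start, stop], 1-based inclusive into the subunit sequence; null for synthetic/chimeric domains without coordinates"
                      },
                      "annotations": {"type": "object", "description": "reserved for externally supplied per-residue annotation strings (e.g. secondary structure, solvent accessibility); passed through verbatim"}
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
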