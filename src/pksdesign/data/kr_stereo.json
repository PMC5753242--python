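{
  "schema_version": "1.0",
  "comment": [
    "Stereochemical outcome table for ketoreductase (KR) types, following the",
    "sequence-motif classification of Keatinge-Clay (Chem. Biol. 14:898-908,",
    "2007) and related KR stereochemistry literature (Caffrey, ChemBioChem",
    "4:654-657, 2003; Reid et al., Biochemistry 42:72-79, 2003).",
    "beta_cip / alpha_cip are the CIP descriptors this package assigns to the",
    "beta-hydroxyl carbon and to a substituted alpha carbon on the standard",
    "acyl-thioester reference substrates (3-hydroxybutanoyl and",
    "2-methyl-3-hydroxypentanoyl). A-type KRs give the (S)-like hydroxyl,",
    "B-type the (R)-like hydroxyl; subtype 1 retains the (2R)-like alpha",
    "configuration, subtype 2 epimerizes to (2S)-like. C-type KRs are",
    "reduction-incompetent: C1 leaves the chain untouched, C2 only epimerizes",
    "the alpha carbon. U (unknown) reduces to a hydroxyl of unspecified",
    "configuration. The table is data so curators can amend it without code",
    "changes."
  ],
  "types": {
    "A1": {"reduces": true,  "beta_cip": "S", "alpha_cip": "R"},
    "A2": {"reduces": true,  "beta_cip": "S", "alpha_cip": "S"},
    "B1": {"reduces": true,  "beta_cip": "R", "alpha_cip": "R"},
    "B2": {"reduces": true,  "beta_cip": "R", "alpha_cip": "S"},
    "C1": {"reduces": false, "beta_cip": null, "alpha_cip": null},
    "C2": {"reduces": false, "beta_cip": null, "alpha_cip": "S"},
    "U":  {"reduces": true,  "beta_cip": null, "alpha_cip": null}
  }
}
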