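# Methods

## Scope and model

`pksdesign` models *cis*-AT type I modular polyketide synthases (PKSs): an
assembly line of modules, each minimally KS–AT–ACP, that grows an acyl chain
by one two-carbon ketide unit per catalytic cycle. The chemistry of one cycle
is fully determined by three curated annotations:

* the AT substrate (which malonyl-CoA analog supplies the α-substituent R′),
* the set of *active* reductive domains KR/DH/ER (which β-carbon oxidation
  state survives: ketone → hydroxyl → α,β-ene → methylene),
* the KR stereotype (which α/β configurations result).

The package simulates this logic module by module, producing a
stereochemically explicit intermediate after every module, and builds three
tools on top of the simulated intermediates: structure similarity search,
subunit sequence search, and a three-step chimera designer. Trans-AT systems,
NRPS hybrids, tailoring enzymes acting on ACP-bound intermediates, and
post-release tailoring are out of scope: the simulated product is the direct
output of the assembly line.

## Chain representation

ACP-tethered intermediates are written as acyl *thioacids* (`R–C(=O)S`, one
S–H sulfur as a minimal surrogate for the phosphopantetheine thiol). Exactly
one such cap exists on every tethered chain, and all reaction operators are
anchored at it, which makes them safe on poly-β-ketone chains: only the
α/β positions of the newest ketide unit are ever touched. Released products
are free acids or lactones.

Similarity scoring uses the same thioacid form for tethered intermediates
(released products are scored as their free acids). Scoring the tethered
form keeps the representation of database entries and the chemistry shown to
the user identical, and it is the convention under which the package's
calibration anchor (the adipic-acid / borrelidin-module-1 score of 0.32, see
below) reproduces.

## Reaction operators

Constitutional transformations are reaction SMARTS stored in
`src/pksdesign/data/operators.json` (versioned, editable without code
changes):

| operator | chemistry |
| --- | --- |
| `extend_template` | decarboxylative condensation; `{rprime}` is replaced per extender |
| `kr_reduce` | β-ketone → β-hydroxyl |
| `dehydrate` | β-hydroxyl + α-H → α,β-ene |
| `enoyl_reduce` | α,β-ene → methylene |
| `c_methylate` / `o_methylate` | cMT at the α-carbon / oMT on the β-hydroxyl |
| `hydrolyze` | thioester → free acid |

Stereochemical outcomes are deliberately *not* encoded in SMARTS product
parity: an atom-map parity pins a local arrangement, not a CIP descriptor,
so the same SMARTS gives different CIP labels on different substituent
classes. Instead the engine applies the constitutional operator, locates the
α/β atoms from the cap anchor, and sets chiral tags until the CIP descriptor
matches the target in the KR table (trying both tags and verifying with the
CIP labeller). Double-bond geometry from DH is set the same way (stereo
atoms + E/Z flag, default E, per-call Z override). TE cyclization is a
graph edit (thioester carbon esterified onto the hydroxyl of the addressed
ketide unit) because it needs a site index, which SMARTS cannot address.

## Stereochemistry table

`data/kr_stereo.json` maps KR types to outcomes, following the
sequence-motif classification of Keatinge-Clay (Chem. Biol. 14:898–908,
2007): A-types give the (S)-like β-hydroxyl and B-types the (R)-like one (on
the standard 3-hydroxyacyl thioester reference substrate); subtype 1 retains
the (2R)-like α-configuration, subtype 2 epimerizes to (2S)-like; C1 is
reduction-inactive and leaves the chain untouched, C2 only epimerizes a
substituted α-carbon; U reduces to a configurationally unspecified
hydroxyl. Outcomes are defined *by CIP descriptor*, which is exact on the
reference substrates and a documented convention elsewhere. The table is
data: a curator can amend it without touching code.

Remaining free conventions, all configurable in `EngineConfig`:
DH geometry (default E — the canonical outcome for B-type-KR-fed DHs), the
α-configuration after ER (default S), and oMT timing (after KR).

## Domain application order

Within one catalytic cycle: condensation, then cMT, then KR → oMT → DH → ER,
each gated by domain presence and the curated activity flag. Iterating
modules repeat the whole cycle `iterations` times. An AT annotated `U`
(unknown specificity) extends with malonyl and marks the chain
low-confidence rather than aborting the simulation.

## Cluster interchange format and corrections

The JSON format (normative documentation in `data/cluster.schema.json`,
enforced in code with path-naming errors) captures cluster → subunit →
module → domain with the curated annotations above. Residue coordinates are
1-based inclusive, the protein feature convention. A document containing an
unrecognized domain kind is truncated at the offending subunit (all later
subunits dropped, `truncated: true`), mirroring an annotation pipeline that
stops at domains it cannot simulate; `strict=true` turns this into an
error.

Curation edits are flat ordered command lists (`CorrectionRecord`):
reorder/remove subunits, set iterations, activity flags, substrates, KR
types, TE modes. Records are idempotent by construction (removal of an
absent subunit is a no-op), so a persistent record can be re-applied on top
of regenerated automatic annotation and a manually corrected cluster stays
corrected.

"Standalone" — a predicate the donor filters use — is defined as: the
subunit carries exactly one non-loading module. A loading-only didomain
subunit is not standalone.

## Similarity search

Two atom-pair representations are exposed.

* `compute_fingerprint` is the explicit Carhart atom-pair descriptor: the
  multiset of (atom type, atom type, shortest-path distance) triples with
  atom type (element, heavy-neighbor count, π electrons);
  `tanimoto` is the multiset Tanimoto Σmin/Σmax (0 when both empty). This
  transparent form is what the oracle-equivalence tests brute-force.
* `similarity_score`, the route used for ranking, computes count-based
  atom-pair fingerprints folded into 2048 bins — the descriptor's standard
  configuration in RDKit — and compares with the count Tanimoto. Under this
  configuration (and the thioacid chain representation) the package
  reproduces 0.32 for adipic acid vs the borrelidin module-1 β-hydroxy
  intermediate, the published anchor for this comparison; that anchor was
  used to fix both conventions, and the acceptance suite recomputes it from
  scratch.

Hits are ranked by descending score with the tie-break (cluster id, module
index), so rankings are invariant to collection order. MCS highlighting uses
a connected, element-exact, bond-order-tolerant maximum common substructure
(RDKit FMCS, 10 s timeout with deterministic best-so-far fallback); because
the MCS engine is edge-based, molecules sharing only a single atom report an
empty map.

## Sequence search

An internal Smith–Waterman/Gotoh aligner (BLOSUM62, gap open 11 / extend 1,
BLAST gap convention: a gap of length L costs 11 + L) scores the query
against every subunit; raw scores are converted to bit scores with the
standard gapped Karlin–Altschul constants λ = 0.267, K = 0.041, so
magnitudes are comparable to familiar protein–protein search output.
E-values are deliberately out of scope (database-size dependent; the
fixture collection is tiny); ranking uses bit score only. Ties break
lexicographically on (cluster id, subunit name). Each hit reports the
fraction of every domain's residue range covered by the aligned span, and
the architecture signature (standalone, AT substrate, active cassette) of
every module, which `filter_hits` predicates consume.

## Chimera design

Step 1 ranks parent modules by intermediate similarity to the target. Step 2
retro-parses the target — restricted to linear (acyclic) carboxylic acids,
the commodity-chemical use case; anything else is a hard error directing the
user to manual planning — into its terminal ketide unit: the free carboxyl
is read as the hydrolyzed thioester, the α-substituent is matched back to a
named extender, the β-carbon is classified on the four-state oxidation
ladder, and the remaining chain is rebuilt as the precursor acyl thioester.
The differences against the parent module become exchanges:

* α-substituent differs → `AT_swap` carrying the required extender;
* β-state differs in ≥ 2 reductive stages → one `reductive_loop_swap`
  carrying the required cassette (and the extender, since loop donors should
  process a matching substrate); exactly one stage → a single `KR_swap` /
  `DH_swap` (an ER-only difference is also a loop swap — an isolated ER
  graft is not a practical exchange);
* no TE on the parent module → `append_TE` (hydrolysis).

If the precursor acyl chain equals a registered starter unit, the plan
records it as a starter re-priming (`starter_override`) — a substrate
substitution at the loading didomain, not a domain exchange. Step 3 ranks
donors for each exchange by bit score of their subunits against the parent
subunit, filtered by the exchange's requirements plus standalone when the
parent itself is standalone (architectural-similarity heuristic).

The plan is then verified: the parent cluster is truncated after the parent
module, the exchanges are grafted (donor KR types are inherited from the
top-ranked donor), and the chimera is simulated. The product is released
only if a TE is present after the exchanges — so a plan missing `append_TE`
verifiably fails to yield a released acid, which keeps the decomposition
minimal (dropping any emitted exchange breaks the target match, a property
the tests check exhaustively on the fixture tasks). Target matching is
stereo-agnostic by default (`stereo_strict` compares isomeric SMILES), since
commodity targets like adipic acid are achiral.

## Fixtures: what they emulate, and what they do not

The bundled collection miniaturizes a published adipic-acid PKS engineering
exercise: a borrelidin fragment (diacid priming unit; standalone malonyl/KR
module 1; malonyl/KR+DH module 2), a 3-module erythromycin-like triketide
synthase, and four donors spanning standalone/multi-module ×
malonyl/methylmalonyl × KR-only/full-cassette, of which exactly two (IdmO-
and SpnB-like) are standalone + malonyl + full cassette.

Sequences are synthetic: one reference block per domain kind, mutated per
subunit at a family-specific rate (5–40%), deterministic for the fixed seed
(default 17). This guarantees self-hits dominate and gives an unambiguous,
reproducible donor ranking, but it does not reproduce natural PKS sequence
statistics (real inter-domain identity structure, linker composition,
low-complexity regions). Domain blocks are 30–90 residues — shortened
relative to natural domains (ACP ≈ 80–100 aa, KS ≈ 420 aa) to keep the
suite fast; alignment behaviour is qualitatively unchanged because scoring
is length-linear. Passing tests therefore demonstrate the *logic* of
ranking, filtering and grafting, not performance on genomic data. Real
sequence ingestion works through the same FASTA/JSON interfaces but is not
exercised in the test suite.

Frozen expected intermediates (`EXPECTED_INTERMEDIATES`) were derived by
manual construction of each product with CIP verification, independent of
the engine code path.

## Numerical and determinism choices

* Canonical isomeric SMILES everywhere; every emitted SMILES
  re-canonicalizes to itself.
* Reaction operator application collapses symmetric duplicate matches by
  canonical SMILES and takes the lexicographically smallest product (the
  anchored operators make multiple distinct products impossible in
  practice).
* Backbone walks (TE cyclization sites, retro-parsing) follow the longest
  remaining carbon path, ties broken by atom index — documented, not
  chemically meaningful, and only reachable on branched backbones.
* Alignment tie-breaks: earliest end cell, substitution preferred over
  gap-in-target over gap-in-query.
* The acceptance script derives all randomness (fixture sequence
  generation) from `--seed`; the chemistry itself is deterministic and
  seed-independent.

## Known limitations

* KR stereochemistry is a per-type lookup; context-dependent KR behaviour
  (substrate-dependent stereo outcomes) is not modelled.
* DH geometry is uniformly E unless overridden; natural Z-selective DHs
  need the per-call override or a correction record on the product side.
* TE cyclization requires a curated site; no regiochemical prediction is
  attempted (default release mode is hydrolysis).
* The retro-parser handles single-unit differences; multi-module extension
  planning (adding several new modules) is not automated.
* Bit scores use fixed gapped Karlin–Altschul constants; they are ranking
  devices here, not significance statistics.
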