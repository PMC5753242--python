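# pksdesign

Simulation and engineering tools for **type I modular polyketide synthases
(PKSs)** — the assembly-line megasynthases behind erythromycin, spinosyn,
borrelidin and an expanding set of engineered commodity chemicals.

Each PKS module (minimally ketosynthase KS, acyltransferase AT and acyl
carrier protein ACP) extends the growing acyl chain by one two-carbon ketide
unit. What that unit looks like is set by three curated annotations: the AT's
extender substrate (malonyl-CoA or one of >20 analogs, supplying the
α-substituent R′), the active subset of the optional reductive cassette
KR/DH/ER (leaving the β-carbon as ketone, hydroxyl, α,β-ene or methylene),
and the KR stereotype (A1/A2/B1/B2/C1/C2, fixing the α/β configurations). A
thioesterase (TE) finally releases the chain as an acid or lactone. Because
this logic is collinear and deterministic, the product of any (natural or
recombined) module sequence can be predicted in silico — which is what this
package does.

`pksdesign` provides, for synthetic biologists designing PKS chimeras:

* **a chemistry engine** — every domain is a reaction operator (SMARTS, kept
  as editable data) plus an explicit stereochemical outcome; simulation
  yields a stereochemically explicit intermediate after every module and the
  released product;
* **structure search** — modules ranked by count-based atom-pair (Carhart)
  Tanimoto similarity between their predicted intermediates and a query
  SMILES, with maximum-common-substructure highlighting;
* **sequence search** — subunits ranked by Smith–Waterman bit score
  (BLOSUM62, affine gaps, Karlin–Altschul normalization), with per-domain
  alignment coverage and architecture filters (standalone subunit, AT
  substrate, complete reductive cassette);
* **a chimera designer** implementing the three-step paradigm: pick a
  truncated parent by intermediate similarity, decompose the remaining
  difference into catalytic domain exchanges, rank donor modules by sequence
  similarity under architecture filters — then verify the plan by
  simulation;
* **a cluster interchange format** — a versioned JSON schema for
  cluster → subunit → module → domain hierarchies, plus idempotent
  correction records that keep manual curation on top of regenerated
  annotation.

A bundled, download-free fixture collection (a borrelidin fragment, a toy
erythromycin-like triketide synthase, and four donor fragments with
synthetic but BLOSUM-alignable sequences) supports all tests and the worked
example below. See `docs/methods.md` for the model, conventions and
limitations.

## Worked example: a PKS that makes adipic acid

Adipic acid (`OC(=O)CCCCC(=O)O`) is a bulk nylon precursor and a classic
PKS-engineering target. Write the fixture collection and search it:

```sh
$ pksdesign fixtures --out fx --seed 17
$ pksdesign search-structure --query "OC(=O)CCCCC(=O)O" --collection fx --top-k 3
cluster_id	module	score	smiles
borrelidin_fragment	1	0.3204	O=C(S)C[C@@H](O)[C@H]1CCC[C@@H]1C(=O)O
borrelidin_fragment	0	0.2195	O=C(O)[C@H]1CCC[C@@H]1C(=O)S
nanchangmycin_fragment	2	0.1912	CCC[C@@H](O)CC(=O)S
```

The best match (atom-pair Tanimoto 0.32) is module 1 of the borrelidin
fragment: its predicted intermediate — the diacid priming unit extended once
with malonyl and KR-reduced to the β-hydroxyl — shares adipic acid's
six-carbon diacid motif. `simulate` shows the per-module chain states
(`tethered 1` = ACP-bound thioester, written with a terminal `C(=O)S` cap):

```sh
$ pksdesign simulate --cluster fx/borrelidin_fragment.json
module	tethered	smiles
0	1	O=C(O)[C@H]1CCC[C@@H]1C(=O)S
1	1	O=C(S)C[C@@H](O)[C@H]1CCC[C@@H]1C(=O)O
2	1	O=C(S)/C=C/C[C@@H](O)[C@H]1CCC[C@@H]1C(=O)O
```

The designer runs the whole paradigm:

```sh
$ pksdesign design --target "OC(=O)CCCCC(=O)O" --collection fx --report markdown
# Chimera design for `OC(=O)CCCCC(=O)O`

Parent: **borrelidin_fragment** module 1 (similarity 0.3204)

Starter re-priming: succinyl

- **reductive_loop_swap** on module 1, AT -> malonyl, cassette {DH, ER, KR}
    - donor IdmO (indanomycin_fragment), bit score 430.25
    - donor SpnB (spinosyn_fragment), bit score 337.04
- **append_TE** on module 1

Predicted product: `O=C(O)CCCCC(=O)O`
Matches target: True
```

Reading the report: the target's terminal ketide unit has no α-substituent
(malonyl) and a fully reduced β-carbon, while the parent module is
malonyl/KR-only — so the designer asks for a donor reductive loop with
active KR+DH+ER and appends a hydrolytic TE. The chain left after removing
that unit is succinyl, a registered starter, recorded as a re-priming of the
loading didomain. Donor ranking (query: the parent subunit) filtered for
standalone subunits with a malonyl AT and a complete cassette returns
exactly the two qualifying fixtures, best bit score first. Simulating the
grafted cluster releases adipic acid, confirming the plan.

## Library use

```python
from pksdesign import design, simulate_cluster
from pksdesign.fixtures import fixture_collection

collection = fixture_collection()
print(simulate_cluster(collection[0]).intermediates[1].smiles)
# O=C(S)C[C@@H](O)[C@H]1CCC[C@@H]1C(=O)O
plan = design("OC(=O)CCCCC(=O)O", collection)
print(plan.predicted_product.smiles)   # O=C(O)CCCCC(=O)O
```

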