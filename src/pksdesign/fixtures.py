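"""Bundled fixture clusters: a download-free miniature PKS collection.

The fixture set mirrors a published adipic-acid PKS engineering exercise at
miniature scale:

* ``borrelidin_fragment`` — loading didomain with the
  trans-1,2-cyclopentanedicarboxylic acid priming unit, a standalone
  malonyl/KR module 1 and a malonyl/KR+DH module 2;
* ``toy_triketide`` — a 3-module erythromycin-like assembly line (propionyl
  start, two methylmalonyl extensions with A1/B1 ketoreductions, TE
  hydrolysis);
* four donor fragments spanning standalone/multi-module x
  malonyl/methylmalonyl x KR-only/full-cassette, of which exactly two
  (``IdmO``-like and ``SpnB``-like) are standalone + malonyl + complete
  reductive cassette.

Amino-acid sequences are synthetic: every domain kind has one reference
block, and each subunit receives that block mutated at a family-specific
rate, so that local-alignment rankings are deterministic for the fixed seed
and self-hits dominate. They are BLOSUM-alignable stand-ins, not natural
sequences.

``EXPECTED_INTERMEDIATES`` freezes hand-derived canonical SMILES (manual
construction with CIP verification) used as simulation oracles.
"""

from __future__ import annotations

import json
import random
from pathlib import Path

from .model import (Cluster, DomainAnnotation, Module, Subunit,
                    validate_cluster, write_cluster_json,
                    write_subunit_fasta)

FIXTURE_SEED = 17

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# block length per domain kind (shortened relative to natural domains to
# keep alignment cost trivial; relative proportions preserved)
BLOCK_LENGTHS = {
    "KS": 90, "AT": 80, "AT_L": 80, "DH": 60, "ER": 60, "KR": 70,
    "cMT": 60, "oMT": 60, "ACP": 30, "TE": 60,
}

# per-subunit mutation rate away from the reference blocks; chosen so the
# ranking BorA2 self > BorA3 > IdmO > SpnB > the rest is unambiguous
MUTATION_RATES = {
    "BorA1": 0.15, "BorA2": 0.05, "BorA3": 0.08,
    "IdmLoad": 0.30, "IdmO": 0.12,
    "SpnLoad": 0.32, "SpnB": 0.22,
    "NanLoad": 0.34, "NanA2": 0.30,
    "MonLoad": 0.36, "MonD": 0.35,
    "EryS1": 0.40, "EryS2": 0.38,
}

# hand-derived oracle SMILES (manual construction, CIP-checked), frozen
EXPECTED_INTERMEDIATES = {
    "borrelidin_fragment": {
        "0": "O=C(O)[C@H]1CCC[C@@H]1C(=O)S",
        "1": "O=C(S)C[C@@H](O)[C@H]1CCC[C@@H]1C(=O)O",
        "2": "O=C(S)/C=C/C[C@@H](O)[C@H]1CCC[C@@H]1C(=O)O",
    },
    "toy_triketide": {
        "0": "CCC(=O)S",
        "1": "CC[C@H](O)[C@@H](C)C(=O)S",
        "2": "CC[C@H](O)[C@@H](C)[C@@H](O)[C@@H](C)C(=O)S",
        "product": "CC[C@H](O)[C@@H](C)[C@@H](O)[C@@H](C)C(=O)O",
    },
}

ADIPIC_ACID = "OC(=O)CCCCC(=O)O"


def _reference_blocks(rng: random.Random) -> dict[str, str]:
    return {kind: "".join(rng.choice(AA20) for _ in range(length))
            for kind, length in sorted(BLOCK_LENGTHS.items())}


def _mutate(block: str, rate: float, rng: random.Random) -> str:
    out = []
    for ch in block:
        if rng.random() < rate:
            out.append(rng.choice(AA20.replace(ch, "")))
        else:
            out.append(ch)
    return "".join(out)


def _build_subunit(name: str, module_specs: list[dict],
                   blocks: dict[str, str], rng: random.Random) -> Subunit:
    """module_specs: [{"index": i, "is_loading": bool, "domains": [(kind,
    attrs), ...]}]; sequence blocks are laid out contiguously in domain
    order."""
    rate = MUTATION_RATES[name]
    seq_parts: list[str] = []
    pos = 0
    modules: list[Module] = []
    for spec in module_specs:
        domains: list[DomainAnnotation] = []
        for kind, attrs in spec["domains"]:
            block = _mutate(blocks[kind], rate, rng)
            start = pos + 1
            pos += len(block)
            seq_parts.append(block)
            domains.append(DomainAnnotation(kind=kind,
                                            residue_range=(start, pos),
                                            **attrs))
        modules.append(Module(index=spec["index"], domains=domains,
                              is_loading=spec.get("is_loading", False),
                              iterations=spec.get("iterations", 1)))
    return Subunit(name=name, sequence="".join(seq_parts), modules=modules)


def _loading(index: int, starter: str) -> dict:
    return {"index": index, "is_loading": True,
            "domains": [("AT_L", {"substrate_specificity": starter}),
                        ("ACP", {})]}


def _extension(index: int, substrate: str, *, kr: str | None = None,
               dh: bool = False, er: bool = False, te: str | None = None,
               kr_active: bool = True) -> dict:
    domains: list = [("KS", {}), ("AT", {"substrate_specificity": substrate})]
    if dh:
        domains.append(("DH", {}))
    if er:
        domains.append(("ER", {}))
    if kr:
        domains.append(("KR", {"kr_type": kr, "active": kr_active}))
    domains.append(("ACP", {}))
    if te:
        domains.append(("TE", {"te_mode": te}))
    return {"index": index, "domains": domains}


def fixture_collection(seed: int = FIXTURE_SEED) -> list[Cluster]:
    """The six bundled clusters, regenerated deterministically from ``seed``."""
    rng = random.Random(seed)
    blocks = _reference_blocks(rng)

    def subunit(name, specs):
        return _build_subunit(name, specs, blocks, rng)

    borrelidin = Cluster(
        id="borrelidin_fragment",
        name="Borrelidin PKS fragment (loading + modules 1-2)",
        provenance={"note": "synthetic fixture modelled on the borrelidin "
                            "assembly line's first modules"},
        subunits=[
            subunit("BorA1", [_loading(
                0, "trans-1,2-cyclopentanedicarboxylic acid")]),
            subunit("BorA2", [_extension(1, "malonyl", kr="B1")]),
            subunit("BorA3", [_extension(2, "malonyl", kr="B1", dh=True)]),
        ])

    toy = Cluster(
        id="toy_triketide",
        name="Toy erythromycin-like triketide synthase",
        known_product=EXPECTED_INTERMEDIATES["toy_triketide"]["product"],
        provenance={"note": "synthetic fixture"},
        subunits=[
            subunit("EryS1", [_loading(0, "propionyl")]),
            subunit("EryS2", [
                _extension(1, "methylmalonyl", kr="A1"),
                _extension(2, "methylmalonyl", kr="B1", te="hydrolysis"),
            ]),
        ])

    indanomycin = Cluster(
        id="indanomycin_fragment",
        name="Indanomycin PKS fragment (IdmO donor)",
        provenance={"note": "synthetic fixture; standalone malonyl module "
                            "with a complete reductive cassette"},
        subunits=[
            subunit("IdmLoad", [_loading(0, "acetyl")]),
            subunit("IdmO", [_extension(1, "malonyl", kr="B1", dh=True,
                                        er=True)]),
        ])

    spinosyn = Cluster(
        id="spinosyn_fragment",
        name="Spinosyn PKS fragment (SpnB donor)",
        provenance={"note": "synthetic fixture; standalone malonyl module "
                            "with a complete reductive cassette"},
        subunits=[
            subunit("SpnLoad", [_loading(0, "acetyl")]),
            subunit("SpnB", [_extension(1, "malonyl", kr="A1", dh=True,
                                        er=True)]),
        ])

    nanchangmycin = Cluster(
        id="nanchangmycin_fragment",
        name="Nanchangmycin PKS fragment (NanA2, multi-module)",
        provenance={"note": "synthetic fixture; full cassette but not a "
                            "standalone subunit"},
        subunits=[
            subunit("NanLoad", [_loading(0, "acetyl")]),
            subunit("NanA2", [
                _extension(1, "malonyl", kr="B1", dh=True, er=True),
                _extension(2, "malonyl", kr="B1"),
            ]),
        ])

    mon = Cluster(
        id="monensin_like_fragment",
        name="Methylmalonyl KR-only donor fragment (MonD)",
        provenance={"note": "synthetic fixture; standalone but "
                            "methylmalonyl and KR-only"},
        subunits=[
            subunit("MonLoad", [_loading(0, "propionyl")]),
            subunit("MonD", [_extension(1, "methylmalonyl", kr="B1")]),
        ])

    clusters = [borrelidin, toy, indanomycin, spinosyn, nanchangmycin, mon]
    for c in clusters:
        validate_cluster(c)
    return clusters


def generate_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Write the fixture set to disk: one cluster JSON per cluster, a FASTA
    of all subunit sequences, and the frozen expected-intermediate oracle.
    Deterministic: the same seed produces byte-identical trees."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clusters = fixture_collection(seed)
    written = []
    for cluster in clusters:
        path = out / f"{cluster.id}.json"
        path.write_text(write_cluster_json(cluster), encoding="utf-8")
        written.append(path)
    fasta = out / "subunits.fasta"
    fasta.write_text(write_subunit_fasta(clusters), encoding="utf-8")
    written.append(fasta)
    expected = out / "expected_intermediates.json"
    expected.write_text(
        json.dumps(EXPECTED_INTERMEDIATES, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    written.append(expected)
    return written


def load_collection(directory: str | Path) -> list[Cluster]:
    """Read every ``*.json`` cluster document in a directory (sorted by
    filename), skipping non-cluster JSON files."""
    from .model import parse_cluster_json
    clusters = []
    for path in sorted(Path(directory).glob("*.json")):
        text = path.read_text(encoding="utf-8")
        if '"$schema_version"' not in text:
            continue
        clusters.append(parse_cluster_json(text))
    return clusters
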