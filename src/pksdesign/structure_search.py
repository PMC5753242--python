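"""Chemical-similarity search over predicted module intermediates.

Modules are ranked by atom-pair Tanimoto similarity between a query molecule
and each module's predicted intermediate, with maximum-common-substructure
(MCS) highlighting of the best matches.

Two atom-pair representations are exposed:

* :func:`compute_fingerprint` — the explicit Carhart atom-pair descriptor, a
  multiset of ``(atom type, atom type, topological distance)`` triples with
  atom type ``(element, heavy-neighbor count, pi electrons)``. This form is
  transparent and is what the descriptor-level API and its tests use.
* :func:`similarity_score` — the scoring route used for ranking: count-based
  atom-pair fingerprints folded into 2048 bins (the standard configuration of
  the descriptor in RDKit) compared with the count Tanimoto. Intermediates
  are scored in their tethered thioacid form; released products as free
  acids/lactones.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem, DataStructs
from rdkit.Chem import GetDistanceMatrix, rdFMCS, rdMolDescriptors

from .chemistry import ChemicalIntermediate, SimulationResult, simulate_cluster
from .errors import InputError
from .model import Cluster

FOLDED_BINS = 2048


def _parse(smiles: str, what: str = "SMILES") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable {what}: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# explicit atom-pair descriptor

def _num_pi_electrons(atom: Chem.Atom) -> int:
    """Pi electrons contributed by an atom's bonds: 2 per extra bond order
    of a double/triple bond, 1 for each aromatic bond beyond sigma."""
    pi = 0
    for bond in atom.GetBonds():
        t = bond.GetBondType()
        if t == Chem.BondType.DOUBLE:
            pi += 2
        elif t == Chem.BondType.TRIPLE:
            pi += 4
        elif t == Chem.BondType.AROMATIC:
            pi += 1
    return pi


def atom_type(atom: Chem.Atom) -> tuple[int, int, int]:
    """Classic atom-pair atom typing: element, number of heavy-atom
    neighbors, number of pi electrons."""
    return (atom.GetAtomicNum(), atom.GetDegree(), _num_pi_electrons(atom))


@dataclass(frozen=True)
class AtomPairFingerprint:
    """Multiset of (type_a, type_b, topological distance) descriptors, with
    the two atom types stored in sorted order so the descriptor is
    symmetric."""

    pairs: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.pairs.values())


def compute_fingerprint(smiles: str) -> AtomPairFingerprint:
    """Enumerate every heavy-atom pair with its shortest-path topological
    distance. A single-heavy-atom molecule has an empty fingerprint."""
    mol = _parse(smiles)
    n = mol.GetNumAtoms()
    pairs: Counter = Counter()
    if n >= 2:
        dmat = GetDistanceMatrix(mol)
        types = [atom_type(a) for a in mol.GetAtoms()]
        for i, j in itertools.combinations(range(n), 2):
            a, b = sorted((types[i], types[j]))
            pairs[(a, b, int(dmat[i][j]))] += 1
    return AtomPairFingerprint(pairs)


def tanimoto(a: AtomPairFingerprint, b: AtomPairFingerprint) -> float:
    """Multiset Tanimoto: sum of per-descriptor minimum counts over sum of
    maximum counts; defined as 0.0 when both fingerprints are empty."""
    inter = sum((a.pairs & b.pairs).values())
    union = sum((a.pairs | b.pairs).values())
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# folded scoring route (used for ranking)

def _folded_fp(mol: Chem.Mol):
    return rdMolDescriptors.GetHashedAtomPairFingerprint(mol,
                                                         nBits=FOLDED_BINS)


def similarity_score(query: Chem.Mol, target: Chem.Mol) -> float:
    """Count Tanimoto over 2048-bin folded atom-pair fingerprints."""
    return DataStructs.TanimotoSimilarity(_folded_fp(query),
                                          _folded_fp(target))


# ---------------------------------------------------------------------------
# search

@dataclass
class StructureHit:
    cluster_id: str
    module_index: int
    intermediate: ChemicalIntermediate
    score: float
    mcs_atom_map: list[tuple[int, int]] = field(default_factory=list)


def search_structures(query: str, collection: list[Cluster], top_k: int = 10,
                      simulations: dict[str, SimulationResult] | None = None,
                      with_mcs: bool = True) -> list[StructureHit]:
    """Rank every module intermediate in the collection by similarity to the
    query.

    Hits are sorted by descending score, ties broken by
    ``(cluster_id, module_index)``; the ranking is therefore invariant to the
    order of the collection. ``simulations`` can supply precomputed results
    keyed by cluster id; missing clusters are simulated on demand.
    """
    qmol = _parse(query, "query SMILES")
    hits: list[StructureHit] = []
    for cluster in collection:
        sim = (simulations or {}).get(cluster.id)
        if sim is None:
            sim = simulate_cluster(cluster)
        for inter in sim.intermediates:
            score = similarity_score(qmol, _parse(inter.smiles))
            hits.append(StructureHit(cluster.id, inter.module_index, inter,
                                     score))
    hits.sort(key=lambda h: (-h.score, h.cluster_id, h.module_index))
    hits = hits[:top_k]
    if with_mcs:
        for hit in hits:
            hit.mcs_atom_map = highlight_mcs(query, hit.intermediate.smiles)
    return hits


# ---------------------------------------------------------------------------
# MCS highlighting

def highlight_mcs(query: str, target: str,
                  timeout: int = 10) -> list[tuple[int, int]]:
    """Atom-index pairs (query, target) of a maximum common connected
    substructure.

    Matching is element-exact and bond-order-tolerant. The MCS engine is
    edge-based, so two molecules sharing only a single atom (or none) yield
    an empty map. Tie-breaks between equally large substructures follow the
    engine's canonical first match, which is deterministic for a fixed input.
    """
    qmol = _parse(query, "query SMILES")
    tmol = _parse(target, "target SMILES")
    res = rdFMCS.FindMCS(
        [qmol, tmol],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareAny,
        timeout=timeout,
    )
    if res.numAtoms == 0 or not res.smartsString:
        return []
    patt = Chem.MolFromSmarts(res.smartsString)
    qmatch = qmol.GetSubstructMatch(patt)
    tmatch = tmol.GetSubstructMatch(patt)
    if not qmatch or not tmatch:
        return []
    return list(zip(qmatch, tmatch))
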