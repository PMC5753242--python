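"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes a different algorithmic route from the code it
checks: alignment scores come from explicit enumeration over chains of
aligned residue pairs, atom-pair fingerprints from a networkx shortest-path
enumeration, and MCS sizes from exhaustive connected-edge-subset search with
subgraph monomorphism.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem

from pksdesign.structure_search import atom_type

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_bruteforce(q: str, t: str, gap_open: int = 11,
                        gap_extend: int = 1) -> int:
    """Optimal local alignment score by enumeration over chains of aligned
    pairs.

    ``B[i][j]`` is the best score of an alignment whose last aligned pair is
    (q[i], t[j]); any earlier pair (i', j') may precede it, paying affine gap
    costs for the skipped residues on either side. No three-state recurrence
    is used.
    """
    n, m = len(q), len(t)
    B = np.zeros((n, m))
    gq = np.array([0] + [gap_open + k * gap_extend for k in range(1, n + 1)],
                  dtype=float)
    gt = np.array([0] + [gap_open + k * gap_extend for k in range(1, m + 1)],
                  dtype=float)
    best = 0.0
    for i in range(n):
        for j in range(m):
            s = BLOSUM62[q[i], t[j]]
            prev = 0.0
            if i > 0 and j > 0:
                gaps = gq[i - 1 - np.arange(i)][:, None] + \
                    gt[j - 1 - np.arange(j)][None, :]
                prev = max(0.0, float((B[:i, :j] - gaps).max()))
            B[i, j] = s + prev
            best = max(best, B[i, j])
    return int(round(best))


def atom_pairs_bruteforce(smiles: str):
    """Atom-pair multiset via networkx shortest paths (independent distance
    computation; shares only the atom-typing function with the package)."""
    from collections import Counter

    mol = Chem.MolFromSmiles(smiles)
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    types = {a.GetIdx(): atom_type(a) for a in mol.GetAtoms()}
    dist = dict(nx.all_pairs_shortest_path_length(g))
    pairs = Counter()
    for i, j in itertools.combinations(range(mol.GetNumAtoms()), 2):
        a, b = sorted((types[i], types[j]))
        pairs[(a, b, dist[i][j])] += 1
    return pairs


def _mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), element=a.GetAtomicNum())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return g


def mcs_size_bruteforce(smiles_a: str, smiles_b: str) -> int:
    """Size (atom count) of the maximum common connected substructure,
    element-exact and bond-order-tolerant, by exhaustive enumeration of
    connected edge subsets of the smaller molecule checked for subgraph
    monomorphism into the other."""
    ga = _mol_graph(Chem.MolFromSmiles(smiles_a))
    gb = _mol_graph(Chem.MolFromSmiles(smiles_b))
    if ga.number_of_edges() > gb.number_of_edges():
        ga, gb = gb, ga
    best = 0
    edges = list(ga.edges())
    node_match = (lambda x, y: x["element"] == y["element"])
    for r in range(1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            sub = nx.Graph()
            for u, v in subset:
                sub.add_node(u, element=ga.nodes[u]["element"])
                sub.add_node(v, element=ga.nodes[v]["element"])
                sub.add_edge(u, v)
            if not nx.is_connected(sub):
                continue
            if sub.number_of_nodes() <= best:
                continue
            gm = GraphMatcher(gb, sub, node_match=node_match)
            if gm.subgraph_is_monomorphic():
                best = sub.number_of_nodes()
    return best
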