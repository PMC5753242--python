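"""Three-step chimeric PKS design.

1. *Parent selection*: find the module whose predicted intermediate is most
   similar to the design target (structure search), and truncate its cluster
   after that module.
2. *Difference decomposition*: retro-parse the target's terminal ketide unit
   (alpha substituent + beta-carbon oxidation state) and compare with the
   parent module's architecture; the difference becomes an ordered list of
   catalytic domain exchanges.
3. *Donor ranking*: for each exchange, rank candidate donor modules by
   sequence similarity of their subunits to the parent subunit, filtered by
   the exchange's architecture requirements (substrate, reductive cassette,
   standalone subunit).

The resulting plan is verified in silico: the grafted cluster is simulated
and its released product compared with the target.

Decomposition is restricted to linear (acyclic) carboxylic-acid targets —
the commodity-chemical use case; anything else raises
:class:`DecompositionError` so the user plans manually rather than receiving
a guess. The rule mapping beta-state differences to exchanges is this
package's formalization: if two or more reductive stages differ, one
``reductive_loop_swap`` is emitted; if exactly one differs, a single-domain
swap (KR or DH; an ER-only difference is also expressed as a loop swap,
since an ER graft is not a practical single-domain exchange).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from rdkit import Chem

from .chemistry import (ChemicalIntermediate, EngineConfig, count_caps,
                        simulate_cluster)
from .errors import DecompositionError, InputError, PKSError
from .model import (Cluster, DomainAnnotation, Module, Subunit,
                    architecture_signature, validate_cluster)
from .registries import Registry, default_extenders, default_starters
from .sequence_search import (ScoringScheme, SequenceHit, filter_hits,
                              search_sequences)
from .structure_search import StructureHit, search_structures

BETA_STATES = ("ketone", "hydroxyl", "enoyl", "methylene")
_STATE_CASSETTE = {
    "ketone": frozenset(),
    "hydroxyl": frozenset({"KR"}),
    "enoyl": frozenset({"KR", "DH"}),
    "methylene": frozenset({"KR", "DH", "ER"}),
}


@dataclass(frozen=True)
class DomainExchange:
    """One catalytic domain exchange required on the parent module."""

    exchange_kind: str  # AT_swap | reductive_loop_swap | KR_swap | DH_swap
    #                     | TE_swap | append_TE
    target_module_index: int
    required_at_substrate: str | None = None
    required_cassette: frozenset[str] = frozenset()
    required_kr_type: str | None = None
    te_mode: str | None = None


@dataclass
class ChimeraPlan:
    """A truncated parent, its exchanges, ranked donors and the simulated
    product of the grafted assembly line."""

    target: str
    parent_cluster_id: str
    parent_module_index: int
    parent_score: float
    exchanges: list[DomainExchange] = field(default_factory=list)
    donors: dict[int, list[SequenceHit]] = field(default_factory=dict)
    starter_override: str | None = None
    predicted_product: ChemicalIntermediate | None = None
    matches_target: bool | None = None


# ---------------------------------------------------------------------------
# step 1: parent selection

def find_parent(target: str, collection: list[Cluster],
                top_k: int = 5) -> list[StructureHit]:
    """Rank candidate truncation points by intermediate similarity to the
    target."""
    return search_structures(target, collection, top_k=top_k, with_mcs=False)


# ---------------------------------------------------------------------------
# step 2: difference decomposition

@dataclass(frozen=True)
class KetideUnit:
    """Retro-parsed terminal two-carbon unit of a linear acid target."""

    extender_name: str
    beta_state: str
    precursor_acyl_smiles: str  # remaining chain as a tethered acyl thioacid


def retro_parse_terminal_unit(target: str,
                              extenders: Registry | None = None
                              ) -> KetideUnit:
    """Split a linear carboxylic acid into its last ketide unit and the
    precursor acyl chain.

    The free carboxyl is read as the hydrolyzed thioester, its alpha
    substituent matched against the extender registry, and the beta carbon's
    oxidation state classified as ketone / hydroxyl / enoyl / methylene.
    """
    extenders = extenders or default_extenders()
    mol = Chem.MolFromSmiles(target)
    if mol is None:
        raise InputError(f"unparsable target SMILES {target!r}")
    if mol.GetRingInfo().NumRings() > 0:
        raise DecompositionError(
            "cyclic targets are not decomposable automatically; plan the "
            "design manually")
    acid = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
    matches = mol.GetSubstructMatches(acid)
    if not matches:
        raise DecompositionError(
            "target has no free carboxylic acid to read as the thioester "
            "end")
    # deterministic choice: first match in canonical atom order
    c1 = matches[0][0]
    carbons = [n.GetIdx() for n in mol.GetAtomWithIdx(c1).GetNeighbors()
               if n.GetAtomicNum() == 6]
    if len(carbons) != 1:
        raise DecompositionError("carboxyl carbon must bear exactly one "
                                 "carbon substituent")
    alpha = carbons[0]
    beta_candidates = [n.GetIdx()
                       for n in mol.GetAtomWithIdx(alpha).GetNeighbors()
                       if n.GetAtomicNum() == 6 and n.GetIdx() != c1]
    if not beta_candidates:
        raise DecompositionError(
            "target is too short to contain a full ketide unit")
    # backbone continues along the longest carbon path
    beta = max(beta_candidates,
               key=lambda j: (_longest_carbon_path(mol, j, {alpha, c1}), -j))
    substituents = [j for j in beta_candidates if j != beta]

    extender_name = _match_extender(mol, alpha, substituents,
                                    {c1, beta}, extenders)
    beta_state = _classify_beta(mol, alpha, beta)
    precursor = _precursor_acyl(mol, c1, alpha, beta)
    return KetideUnit(extender_name, beta_state, precursor)


def _longest_carbon_path(mol: Chem.Mol, start: int,
                         blocked: set[int]) -> int:
    best = 0
    stack = [(start, frozenset(blocked) | {start}, 1)]
    while stack:
        node, visited, depth = stack.pop()
        best = max(best, depth)
        for n in mol.GetAtomWithIdx(node).GetNeighbors():
            j = n.GetIdx()
            if j not in visited and n.GetAtomicNum() == 6:
                stack.append((j, visited | {j}, depth + 1))
    return best


def _match_extender(mol, alpha, substituents, backbone_neighbors,
                    extenders: Registry) -> str:
    """Map the alpha substituent branch back to a named extender unit."""
    # alpha may also carry O/N substituents (hydroxymalonyl etc.)
    hetero = [n.GetIdx() for n in mol.GetAtomWithIdx(alpha).GetNeighbors()
              if n.GetAtomicNum() not in (1, 6)]
    branch_roots = list(substituents) + hetero
    if not branch_roots:
        return "malonyl"
    if len(branch_roots) > 1:
        raise DecompositionError(
            "alpha carbon carries more than one substituent; no single "
            "extender unit installs that")
    branch_atoms = _collect_branch(mol, branch_roots[0],
                                   {alpha} | set(backbone_neighbors))
    frag = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(branch_atoms),
                                    rootedAtAtom=branch_roots[0],
                                    canonical=True)
    frag_canon = Chem.CanonSmiles(frag)
    for name, unit in extenders.items():
        if not unit.alpha_substituent_smiles:
            continue
        if Chem.CanonSmiles(unit.alpha_substituent_smiles) == frag_canon:
            return name
    raise DecompositionError(
        f"alpha substituent {frag_canon!r} matches no registered extender "
        f"unit")


def _collect_branch(mol, root, blocked):
    atoms = set()
    stack = [root]
    while stack:
        i = stack.pop()
        if i in atoms or i in blocked:
            continue
        atoms.add(i)
        stack.extend(n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors())
    return atoms


def _classify_beta(mol: Chem.Mol, alpha: int, beta: int) -> str:
    bond = mol.GetBondBetweenAtoms(alpha, beta)
    if bond.GetBondType() == Chem.BondType.DOUBLE:
        return "enoyl"
    batom = mol.GetAtomWithIdx(beta)
    for n in batom.GetNeighbors():
        if n.GetAtomicNum() == 8:
            b = mol.GetBondBetweenAtoms(beta, n.GetIdx())
            if b.GetBondType() == Chem.BondType.DOUBLE:
                return "ketone"
            if n.GetTotalNumHs() == 1:
                return "hydroxyl"
    return "methylene"


def _precursor_acyl(mol: Chem.Mol, c1: int, alpha: int, beta: int) -> str:
    """The chain before the last extension, as a tethered acyl thioacid:
    drop C1 + Calpha (and C1's oxygens, alpha substituents), restore the
    beta carbon to a thioester carbonyl."""
    drop = {c1, alpha}
    for n in mol.GetAtomWithIdx(c1).GetNeighbors():
        if n.GetAtomicNum() == 8:
            drop.add(n.GetIdx())
    for n in mol.GetAtomWithIdx(alpha).GetNeighbors():
        if n.GetIdx() not in (c1, beta):
            drop |= _collect_branch(mol, n.GetIdx(), {alpha})
    rw = Chem.RWMol(mol)
    # strip any oxidation at beta: it becomes the new thioester carbonyl
    for n in list(rw.GetAtomWithIdx(beta).GetNeighbors()):
        if n.GetAtomicNum() == 8:
            drop.add(n.GetIdx())
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    # beta kept its position relative to removals below it
    new_beta = beta - sum(1 for i in drop if i < beta)
    batom = rw.GetAtomWithIdx(new_beta)
    batom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    batom.SetNumExplicitHs(0)
    batom.SetNoImplicit(False)
    o = rw.AddAtom(Chem.Atom(8))
    s = rw.AddAtom(Chem.Atom(16))
    rw.AddBond(new_beta, o, Chem.BondType.DOUBLE)
    rw.AddBond(new_beta, s, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise DecompositionError(
            f"could not rebuild the precursor acyl chain: {exc}") from exc
    if count_caps(out) != 1:
        raise DecompositionError(
            "precursor chain did not reduce to a single-thioester acyl "
            "group")
    return Chem.MolToSmiles(out)


def match_starter(acyl_thioester_smiles: str,
                  starters: Registry | None = None) -> str | None:
    """Name of the registered starter whose tethered acyl group equals the
    given chain (stereo-agnostic); None when no starter matches."""
    starters = starters or default_starters()
    want = Chem.CanonSmiles(_strip_stereo(acyl_thioester_smiles))
    for name, unit in starters.items():
        if Chem.CanonSmiles(_strip_stereo(unit.acyl_smiles)) == want:
            return name
    return None


def _strip_stereo(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def diff_to_exchanges(target: str, parent_intermediate: ChemicalIntermediate,
                      parent_module: Module,
                      extenders: Registry | None = None
                      ) -> list[DomainExchange]:
    """Decompose the difference between the target's terminal ketide unit
    and the parent module's architecture into domain exchanges.

    Returns an empty list when the architectures already agree (and the
    parent carries a TE). Emits, in order: an ``AT_swap`` when the alpha
    substituents differ, a reductive-stage exchange when the beta oxidation
    states differ, and ``append_TE`` (hydrolysis) when the parent module has
    no TE.
    """
    unit = retro_parse_terminal_unit(target, extenders)
    sig = architecture_signature(parent_module)
    exchanges: list[DomainExchange] = []

    if unit.extender_name != sig.at_substrate:
        exchanges.append(DomainExchange(
            "AT_swap", parent_module.index,
            required_at_substrate=unit.extender_name))

    want = _STATE_CASSETTE[unit.beta_state]
    have = frozenset(sig.cassette)
    differing = want ^ have
    if differing:
        if len(differing) == 1 and differing <= {"KR", "DH"}:
            kind = "KR_swap" if differing == {"KR"} else "DH_swap"
        else:
            kind = "reductive_loop_swap"
        exchanges.append(DomainExchange(
            kind, parent_module.index,
            required_at_substrate=unit.extender_name,
            required_cassette=want))

    te = parent_module.domain("TE")
    if te is None or not te.active:
        exchanges.append(DomainExchange(
            "append_TE", parent_module.index, te_mode="hydrolysis"))
    return exchanges


# ---------------------------------------------------------------------------
# step 3: donor ranking

def rank_donors(exchange: DomainExchange, parent_subunit_sequence: str,
                collection: list[Cluster],
                scheme: ScoringScheme | None = None,
                top_k: int | None = None,
                require_standalone: bool | None = None) -> list[SequenceHit]:
    """Rank donor subunits for one exchange by bit score against the parent
    subunit, keeping only subunits with a module matching the exchange's
    architecture requirements."""
    hits = search_sequences(parent_subunit_sequence, collection, scheme)
    kwargs: dict = {}
    if exchange.required_at_substrate is not None:
        kwargs["at_substrate"] = exchange.required_at_substrate
    if exchange.exchange_kind == "reductive_loop_swap":
        kwargs["cassette"] = set(exchange.required_cassette)
    elif exchange.exchange_kind == "DH_swap":
        kwargs["cassette"] = {"DH"}
        kwargs.pop("at_substrate", None)  # a DH donor need not share the AT
    elif exchange.exchange_kind == "KR_swap":
        kwargs["cassette"] = {"KR"}
    if require_standalone is not None:
        kwargs["standalone"] = require_standalone
    hits = filter_hits(hits, **kwargs)
    return hits if top_k is None else hits[:top_k]


# ---------------------------------------------------------------------------
# plan simulation

def _find_cluster(collection: list[Cluster], cluster_id: str) -> Cluster:
    for c in collection:
        if c.id == cluster_id:
            return c
    raise PKSError(f"cluster {cluster_id!r} not in collection")


def _truncate_after(cluster: Cluster, module_index: int) -> Cluster:
    out = copy.deepcopy(cluster)
    subunits: list[Subunit] = []
    for su in out.subunits:
        keep = [m for m in su.modules if m.index <= module_index]
        if keep:
            su.modules = keep
            subunits.append(su)
    out.subunits = subunits
    out.id = f"{cluster.id}+chimera"
    out.known_product = None
    return out


def _donor_module(donor: SequenceHit | None, collection: list[Cluster],
                  required_cassette: frozenset[str]) -> Module | None:
    if donor is None:
        return None
    cluster = _find_cluster(collection, donor.cluster_id)
    for su in cluster.subunits:
        if su.name != donor.subunit_name:
            continue
        for mod in su.modules:
            sig = architecture_signature(mod, su)
            if not mod.is_loading and required_cassette <= sig.cassette:
                return mod
    return None


def apply_exchanges(parent: Cluster, module_index: int,
                    exchanges: list[DomainExchange],
                    donors: dict[int, SequenceHit | None] | None = None,
                    collection: list[Cluster] | None = None) -> Cluster:
    """Graft the exchanged domains onto the truncated parent cluster.

    Reductive domains grafted from a donor module keep the donor's KR type
    and activity flags; without a resolved donor the required cassette is
    installed with default annotations (KR type B1). Grafted domains carry no
    residue coordinates.
    """
    chimera = _truncate_after(parent, module_index)
    _, module = chimera.module(module_index)
    for i, ex in enumerate(exchanges):
        donor_hit = (donors or {}).get(i)
        if ex.exchange_kind == "AT_swap":
            module.domain("AT").substrate_specificity = \
                ex.required_at_substrate
        elif ex.exchange_kind in ("reductive_loop_swap", "KR_swap",
                                  "DH_swap"):
            dmod = _donor_module(donor_hit, collection or [],
                                 ex.required_cassette) \
                if donor_hit is not None else None
            _graft_cassette(module, ex.required_cassette or
                            frozenset({ex.exchange_kind[:2]}), dmod)
        elif ex.exchange_kind in ("append_TE", "TE_swap"):
            te = module.domain("TE")
            if te is None:
                acp_pos = max(i for i, d in enumerate(module.domains)
                              if d.kind == "ACP")
                module.domains.insert(acp_pos + 1, DomainAnnotation(
                    kind="TE", te_mode=ex.te_mode or "hydrolysis"))
            else:
                te.te_mode = ex.te_mode or "hydrolysis"
                te.active = True
        else:
            raise PKSError(f"unknown exchange kind {ex.exchange_kind!r}")
    validate_cluster(chimera)
    return chimera


def _graft_cassette(module: Module, required: frozenset[str],
                    donor_module: Module | None) -> None:
    order = {"KR": 2, "DH": 1, "ER": 0}  # conventional DH-ER-KR layout
    for kind in sorted(required, key=lambda k: order[k]):
        dom = module.domain(kind)
        if dom is None:
            dom = DomainAnnotation(kind=kind)
            ks_pos = next(i for i, d in enumerate(module.domains)
                          if d.kind == "AT")
            module.domains.insert(ks_pos + 1, dom)
        dom.active = True
        if kind == "KR":
            donor_kr = donor_module.domain("KR") if donor_module else None
            dom.kr_type = donor_kr.kr_type if donor_kr else (dom.kr_type
                                                             or "B1")
    for kind in ("KR", "DH", "ER"):
        dom = module.domain(kind)
        if dom is not None and kind not in required:
            dom.active = False


def simulate_chimera(plan: ChimeraPlan, collection: list[Cluster],
                     starters: Registry | None = None,
                     extenders: Registry | None = None,
                     config: EngineConfig | None = None
                     ) -> ChemicalIntermediate | None:
    """Simulate the planned chimera and return its released product (or the
    final tethered intermediate when no TE is present after the exchanges)."""
    parent = _find_cluster(collection, plan.parent_cluster_id)
    donors = {i: (plan.donors.get(i, [None]) or [None])[0]
              for i in range(len(plan.exchanges))}
    chimera = apply_exchanges(parent, plan.parent_module_index,
                              plan.exchanges, donors, collection)
    if plan.starter_override:
        starters = starters or default_starters()
        starters.get_unit(plan.starter_override)
        _, loading = chimera.module(0)
        loading.domain("AT_L").substrate_specificity = plan.starter_override
    result = simulate_cluster(chimera, starters, extenders, config)
    return result.product if result.product is not None \
        else result.intermediates[-1]


# ---------------------------------------------------------------------------
# orchestration

def design(target: str, collection: list[Cluster],
           top_parents: int = 3, top_donors: int = 5,
           scheme: ScoringScheme | None = None,
           stereo_strict: bool = False) -> ChimeraPlan:
    """Run the full three-step paradigm and verify the plan by simulation.

    Target matching is stereo-agnostic by default (``stereo_strict=True``
    compares isomeric SMILES exactly).
    """
    parents = find_parent(target, collection, top_k=top_parents)
    if not parents:
        raise PKSError("empty collection: no parent candidates")
    best = parents[0]
    parent_cluster = _find_cluster(collection, best.cluster_id)
    parent_subunit, parent_module = parent_cluster.module(best.module_index)

    exchanges = diff_to_exchanges(target, best.intermediate, parent_module)
    unit = retro_parse_terminal_unit(target)
    starter_override = match_starter(unit.precursor_acyl_smiles)

    plan = ChimeraPlan(
        target=target,
        parent_cluster_id=best.cluster_id,
        parent_module_index=best.module_index,
        parent_score=best.score,
        exchanges=exchanges,
        starter_override=starter_override,
    )
    for i, ex in enumerate(exchanges):
        if ex.exchange_kind == "append_TE":
            plan.donors[i] = []
            continue
        plan.donors[i] = rank_donors(
            ex, parent_subunit.sequence, collection, scheme,
            top_k=top_donors,
            require_standalone=parent_subunit.standalone or None)
    plan.predicted_product = simulate_chimera(plan, collection)
    if plan.predicted_product is not None:
        got = plan.predicted_product.smiles
        if stereo_strict:
            plan.matches_target = Chem.CanonSmiles(got) == \
                Chem.CanonSmiles(target)
        else:
            plan.matches_target = _strip_stereo(got) == _strip_stereo(target)
    return plan
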