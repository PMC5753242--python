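"""Domain-by-domain simulation of polyketide chain assembly.

Each catalytic domain is modelled as a chemical transformation on the growing
acyl chain and the transformations are composed module by module, yielding a
stereochemically explicit intermediate after every module and, when a
thioesterase is present, the released acid or lactone.

Representation convention
-------------------------
ACP-tethered intermediates carry a minimal thioester cap: the acyl chain is
written as a thioacid (``R-C(=O)S``, one S-H sulfur standing in for the
phosphopantetheine arm). Exactly one such cap is present on every tethered
intermediate, and all reaction operators are anchored at it, so a
poly-beta-ketone chain is only ever modified at its alpha/beta positions.
Released products are free acids or lactones with no cap.

Constitutional changes are applied through reaction SMARTS operators stored
in ``data/operators.json``; stereochemical outcomes (KR CIP targets, DH
double-bond geometry, ER alpha configuration) are set afterwards on the
matched atoms, targeting the CIP descriptors in the shipped KR table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import (ChemistryError, ReleaseError, StateError, SubstrateError,
                     ValidationError)
from .model import Cluster, Module
from .registries import (KrStereoRule, Registry, default_extenders,
                         default_starters, kr_stereo_rules,
                         reaction_operators)

RDLogger.DisableLog("rdApp.*")

# thioester cap: the one S-H sulfur bonded to an acyl carbonyl
CAP_SMARTS = Chem.MolFromSmarts("[SX2;H1][CX3]=[OX1]")


@dataclass(frozen=True)
class ChemicalIntermediate:
    """A stereochemically explicit chain state.

    ``tethered`` distinguishes ACP-bound thioesters (thioacid-capped) from
    released acids/lactones. ``low_confidence`` marks chains that passed
    through an AT of unknown specificity (simulated as malonyl).
    """

    smiles: str
    tethered: bool
    module_index: int
    low_confidence: bool = False

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class SimulationResult:
    """Per-module intermediates (loading included) plus the released product
    when the final module carries an active TE."""

    cluster_id: str
    intermediates: list[ChemicalIntermediate] = field(default_factory=list)
    product: ChemicalIntermediate | None = None


@dataclass
class EngineConfig:
    """Tunable conventions the stereochemistry literature leaves open."""

    dh_geometry: str = "E"          # or "Z"
    er_alpha_cip: str = "S"         # CIP of the alpha carbon after ER
    omt_after_kr: bool = True


def canonical(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ChemistryError(f"unparsable SMILES {smiles!r}")
    return m


def count_caps(mol: Chem.Mol) -> int:
    return len(mol.GetSubstructMatches(CAP_SMARTS))


def _require_tethered(chain: ChemicalIntermediate) -> Chem.Mol:
    if not chain.tethered:
        raise StateError(
            "operation requires an ACP-tethered (thioester-capped) chain; "
            "got a released product")
    return _mol(chain.smiles)


_RXN_CACHE: dict[str, AllChem.ChemicalReaction] = {}


def _reaction(smarts: str) -> AllChem.ChemicalReaction:
    rxn = _RXN_CACHE.get(smarts)
    if rxn is None:
        rxn = AllChem.ReactionFromSmarts(smarts)
        _RXN_CACHE[smarts] = rxn
    return rxn


def _run_operator(smarts: str, mol: Chem.Mol, what: str) -> Chem.Mol:
    """Apply one reaction operator; the unique product is returned.

    Operators are anchored at the single thioester cap, so at most one
    distinct product can arise; symmetric duplicate matches are collapsed by
    canonical SMILES.
    """
    products = _reaction(smarts).RunReactants((mol,))
    unique: dict[str, Chem.Mol] = {}
    for (p,) in products:
        try:
            Chem.SanitizeMol(p)
        except Exception:
            continue
        unique.setdefault(Chem.MolToSmiles(p), p)
    if not unique:
        raise SubstrateError(
            f"{what}: chain {Chem.MolToSmiles(mol)!r} lacks the required "
            f"functional group")
    smi = sorted(unique)[0]
    return _mol(smi)


# ---------------------------------------------------------------------------
# stereochemistry helpers

def _assign_cip(mol: Chem.Mol, idx: int, target: str) -> bool:
    """Set the chiral tag at ``idx`` so its CIP descriptor equals ``target``.

    Returns False (leaving the atom unset) when the carbon is not a genuine
    stereocenter, e.g. a beta carbon flanked by identical substituents.
    """
    atom = mol.GetAtomWithIdx(idx)
    atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    atom = mol.GetAtomWithIdx(idx)
    if not atom.HasProp("_CIPCode"):
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        return False
    if atom.GetProp("_CIPCode") != target:
        atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return True


def _cap_match(mol: Chem.Mol, smarts: str) -> tuple[int, ...]:
    patt = Chem.MolFromSmarts(smarts)
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        raise SubstrateError(
            f"expected pattern {smarts!r} in {Chem.MolToSmiles(mol)!r}")
    return matches[0]


# ---------------------------------------------------------------------------
# domain operations

def load_starter(loading_module: Module,
                 starters: Registry | None = None) -> ChemicalIntermediate:
    """Prime the assembly line: the AT_L-selected starter acyl group becomes
    the tethered chain of module 0."""
    if not loading_module.is_loading:
        raise ValidationError("load_starter requires the loading module")
    starters = starters or default_starters()
    at_l = loading_module.domain("AT_L")
    if at_l is None or not at_l.substrate_specificity:
        raise ValidationError("loading module has no AT_L substrate")
    unit = starters.get_unit(at_l.substrate_specificity)
    mol = _mol(unit.acyl_smiles)
    if count_caps(mol) != 1:
        raise ChemistryError(
            f"starter {unit.name!r} must carry exactly one thioester cap")
    return ChemicalIntermediate(canonical(mol), tethered=True,
                                module_index=loading_module.index)


def extend_chain(chain: ChemicalIntermediate, extender) -> ChemicalIntermediate:
    """KS-catalyzed decarboxylative condensation with a malonyl-CoA analog.

    The extender's alpha carbon attacks the chain's thioester carbonyl: the
    backbone grows by exactly two carbons and the new alpha carbon carries
    the extender's R' substituent.
    """
    mol = _require_tethered(chain)
    frag = extender.alpha_substituent_smiles
    template = reaction_operators()["extend_template"]
    smarts = template.replace("{rprime}", f"({frag})" if frag else "")
    out = _run_operator(smarts, mol, f"extension with {extender.name}")
    return replace(chain, smiles=canonical(out))


def kr_reduce(chain: ChemicalIntermediate,
              rule: KrStereoRule) -> ChemicalIntermediate:
    """Ketoreduction of the beta-ketone with the stereochemical outcome of
    the given KR type; C-types leave the constitution unchanged (C2
    epimerizes a substituted alpha carbon only)."""
    mol = _require_tethered(chain)
    if not rule.reduces:
        if rule.alpha_cip:  # C2: epimerization without reduction
            match = mol.GetSubstructMatches(Chem.MolFromSmarts(
                "[SX2;H1][CX3](=[OX1])[CX4][CX3]=[OX1]"))
            if match:
                alpha = match[0][3]
                if mol.GetAtomWithIdx(alpha).GetDegree() == 3:
                    _assign_cip(mol, alpha, rule.alpha_cip)
        return replace(chain, smiles=canonical(mol))
    out = _run_operator(reaction_operators()["kr_reduce"], mol,
                        "KR reduction")
    s, c1, o1, alpha, beta = _cap_match(
        out, "[SX2;H1][CX3](=[OX1])[CX4][CX4;$(C[OX2H1])]")
    if rule.beta_cip:
        _assign_cip(out, beta, rule.beta_cip)
    if rule.alpha_cip and out.GetAtomWithIdx(alpha).GetDegree() == 3:
        _assign_cip(out, alpha, rule.alpha_cip)
    Chem.AssignStereochemistry(out, cleanIt=True, force=True)
    return replace(chain, smiles=canonical(out))


def dehydrate(chain: ChemicalIntermediate,
              geometry: str = "E") -> ChemicalIntermediate:
    """DH-catalyzed syn elimination of the beta-hydroxyl to the
    alpha,beta-enoyl thioester; trans (E) geometry by default."""
    mol = _require_tethered(chain)
    out = _run_operator(reaction_operators()["dehydrate"], mol,
                        "dehydration")
    s, c1, o1, alpha, beta = _cap_match(
        out, "[SX2;H1][CX3](=[OX1])[CX3]=[CX3]")
    bond = out.GetBondBetweenAtoms(alpha, beta)
    partner = [n.GetIdx() for n in out.GetAtomWithIdx(beta).GetNeighbors()
               if n.GetIdx() != alpha and n.GetAtomicNum() > 1]
    if partner:
        if bond.GetBeginAtomIdx() == alpha:
            bond.SetStereoAtoms(c1, min(partner))
        else:
            bond.SetStereoAtoms(min(partner), c1)
        bond.SetStereo(Chem.BondStereo.STEREOTRANS if geometry == "E"
                       else Chem.BondStereo.STEREOCIS)
        Chem.SetDoubleBondNeighborDirections(out)
    out = _mol(Chem.MolToSmiles(out))
    return replace(chain, smiles=canonical(out))


def enoyl_reduce(chain: ChemicalIntermediate,
                 alpha_cip: str = "S") -> ChemicalIntermediate:
    """ER-catalyzed saturation of the alpha,beta double bond; a substituted
    alpha carbon is set to the configured CIP outcome (default S)."""
    mol = _require_tethered(chain)
    out = _run_operator(reaction_operators()["enoyl_reduce"], mol,
                        "enoyl reduction")
    s, c1, o1, alpha = _cap_match(out, "[SX2;H1][CX3](=[OX1])[CX4]")
    if out.GetAtomWithIdx(alpha).GetDegree() == 3:
        _assign_cip(out, alpha, alpha_cip)
    Chem.AssignStereochemistry(out, cleanIt=True, force=True)
    return replace(chain, smiles=canonical(out))


def alpha_methylate(chain: ChemicalIntermediate,
                    mode: str = "cMT") -> ChemicalIntermediate:
    """cMT adds a methyl at the alpha carbon (requires an alpha hydrogen);
    oMT O-methylates the beta-hydroxyl."""
    mol = _require_tethered(chain)
    if mode == "cMT":
        op = reaction_operators()["c_methylate"]
        what = "C-methylation (alpha carbon has no hydrogen)"
    elif mode == "oMT":
        op = reaction_operators()["o_methylate"]
        what = "O-methylation (no beta-hydroxyl)"
    else:
        raise ChemistryError(f"unknown methyltransferase mode {mode!r}")
    out = _run_operator(op, mol, what)
    return replace(chain, smiles=canonical(out))


def release_product(chain: ChemicalIntermediate, mode: str = "hydrolysis",
                    site: int | None = None) -> ChemicalIntermediate:
    """TE-catalyzed chain release: hydrolysis to the free acid, or
    cyclization to the lactone closed onto the hydroxyl of the addressed
    ketide unit (1-based, counted from the thioester end)."""
    mol = _require_tethered(chain)
    if mode == "hydrolysis":
        out = _run_operator(reaction_operators()["hydrolyze"], mol,
                            "hydrolysis")
    elif mode == "cyclization":
        out = _cyclize(mol, site)
    else:
        raise ReleaseError(f"unknown TE mode {mode!r}")
    return ChemicalIntermediate(canonical(out), tethered=False,
                                module_index=chain.module_index,
                                low_confidence=chain.low_confidence)


def _backbone_walk(mol: Chem.Mol) -> list[int]:
    """Carbon backbone from the thioester carbonyl, following at each branch
    the neighbor with the longest remaining simple carbon path (ties broken
    by atom index, documented and deterministic)."""
    s, c1, o1 = _cap_match(mol, "[SX2;H1][CX3]=[OX1]")

    def longest_from(idx: int, visited: frozenset[int]) -> int:
        best = 0
        for n in mol.GetAtomWithIdx(idx).GetNeighbors():
            j = n.GetIdx()
            if j in visited or n.GetAtomicNum() != 6:
                continue
            best = max(best, 1 + longest_from(j, visited | {j}))
        return best

    backbone = [c1]
    visited = {s, c1}
    current = c1
    while True:
        candidates = [n.GetIdx()
                      for n in mol.GetAtomWithIdx(current).GetNeighbors()
                      if n.GetIdx() not in visited and n.GetAtomicNum() == 6]
        if not candidates:
            break
        current = max(
            candidates,
            key=lambda j: (longest_from(j, frozenset(visited | {j})), -j))
        backbone.append(current)
        visited.add(current)
    return backbone


def _cyclize(mol: Chem.Mol, site: int | None) -> Chem.Mol:
    if site is None or site < 1:
        raise ReleaseError("cyclization requires a 1-based ketide-unit site")
    backbone = _backbone_walk(mol)
    beta_pos = 2 * site
    if beta_pos >= len(backbone):
        raise ReleaseError(
            f"ketide unit {site} is beyond the chain ({len(backbone)} "
            f"backbone carbons)")
    carbon = backbone[beta_pos]
    hydroxyl = None
    for n in mol.GetAtomWithIdx(carbon).GetNeighbors():
        if (n.GetAtomicNum() == 8 and n.GetTotalNumHs() == 1
                and n.GetDegree() == 1):
            hydroxyl = n.GetIdx()
            break
    if hydroxyl is None:
        raise ReleaseError(
            f"ketide unit {site} bears no free hydroxyl to cyclize onto")
    s, c1, _ = _cap_match(mol, "[SX2;H1][CX3]=[OX1]")
    rw = Chem.RWMol(mol)
    rw.RemoveBond(s, c1)
    rw.RemoveAtom(s)
    # removal may shift indices of atoms above s
    shift = (lambda i: i - 1 if i > s else i)
    rw.AddBond(shift(c1), shift(hydroxyl), Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(shift(hydroxyl)).SetNumExplicitHs(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


# ---------------------------------------------------------------------------
# whole-module / whole-cluster simulation

def simulate_module(chain: ChemicalIntermediate, module: Module,
                    extenders: Registry | None = None,
                    config: EngineConfig | None = None
                    ) -> ChemicalIntermediate:
    """One catalytic cycle of an extension module, repeated ``iterations``
    times: condensation, then cMT, then the reductive cascade KR -> DH -> ER
    (each gated by presence and the curated activity flag)."""
    extenders = extenders or default_extenders()
    config = config or EngineConfig()
    at = module.domain("AT")
    if at is None or not at.substrate_specificity:
        raise SubstrateError("module has no AT substrate annotation",
                             module.index)
    low_confidence = chain.low_confidence
    if at.substrate_specificity == "U":
        extender = extenders.get_unit("malonyl")
        low_confidence = True
    else:
        extender = extenders.get_unit(at.substrate_specificity)

    for _ in range(module.iterations):
        chain = extend_chain(chain, extender)
        cmt = module.domain("cMT")
        if cmt is not None and cmt.active:
            chain = alpha_methylate(chain, "cMT")
        kr = module.domain("KR")
        if kr is not None and kr.active:
            chain = kr_reduce(chain, kr_stereo_rules().get_unit(kr.kr_type))
        omt = module.domain("oMT")
        if omt is not None and omt.active and config.omt_after_kr:
            chain = alpha_methylate(chain, "oMT")
        dh = module.domain("DH")
        if dh is not None and dh.active:
            chain = dehydrate(chain, config.dh_geometry)
        er = module.domain("ER")
        if er is not None and er.active:
            chain = enoyl_reduce(chain, config.er_alpha_cip)
    return replace(chain, module_index=module.index,
                   low_confidence=low_confidence)


def simulate_cluster(cluster: Cluster,
                     starters: Registry | None = None,
                     extenders: Registry | None = None,
                     config: EngineConfig | None = None) -> SimulationResult:
    """Simulate every module in catalytic order.

    Returns one intermediate per module (loading included). If the final
    module carries an active TE the released product is included. Substrate
    errors are re-raised with the failing module's index attached; a
    truncated cluster simply simulates up to its truncation point.
    """
    result = SimulationResult(cluster_id=cluster.id)
    chain: ChemicalIntermediate | None = None
    last_module: Module | None = None
    for subunit, module in cluster.iter_modules():
        try:
            if module.is_loading:
                chain = load_starter(module, starters)
            else:
                if chain is None:
                    raise StateError("no loading module preceded extension")
                chain = simulate_module(chain, module, extenders, config)
        except ChemistryError as exc:
            if exc.module_index is None:
                raise type(exc)(str(exc), module_index=module.index) from exc
            raise
        result.intermediates.append(chain)
        last_module = module
    if last_module is not None and chain is not None:
        te = last_module.domain("TE")
        if te is not None and te.active:
            result.product = release_product(chain, te.te_mode,
                                             te.cyclization_site)
    return result
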