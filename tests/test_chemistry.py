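"""Domain-level chemistry: each operation against hand-derived products, the
stereochemistry table, and whole-chain invariants."""

import pytest
from rdkit import Chem

from pksdesign.chemistry import (CAP_SMARTS, ChemicalIntermediate,
                                 alpha_methylate, count_caps, dehydrate,
                                 enoyl_reduce, extend_chain, kr_reduce,
                                 load_starter, release_product,
                                 simulate_cluster)
from pksdesign.errors import (RegistryError, ReleaseError, StateError,
                              SubstrateError)
from pksdesign.fixtures import EXPECTED_INTERMEDIATES
from pksdesign.model import DomainAnnotation, Module
from pksdesign.registries import (default_extenders, default_starters,
                                  kr_stereo_rules)


def chain(smiles, tethered=True):
    return ChemicalIntermediate(Chem.CanonSmiles(smiles), tethered, 0)


def canon(smiles):
    return Chem.CanonSmiles(smiles)


EXT = default_extenders()
KR = kr_stereo_rules()


# ---------------------------------------------------------------------------
# loading

def test_load_starter_propionyl():
    mod = Module(index=0, is_loading=True, domains=[
        DomainAnnotation("AT_L", substrate_specificity="propionyl"),
        DomainAnnotation("ACP")])
    inter = load_starter(mod)
    assert inter.smiles == canon("CCC(S)=O")
    assert inter.tethered and inter.module_index == 0


def test_load_starter_diacid_keeps_distal_carboxyl():
    mod = Module(index=0, is_loading=True, domains=[
        DomainAnnotation("AT_L", substrate_specificity=
                         "trans-1,2-cyclopentanedicarboxylic acid"),
        DomainAnnotation("ACP")])
    inter = load_starter(mod)
    mol = Chem.MolFromSmiles(inter.smiles)
    assert count_caps(mol) == 1
    assert mol.HasSubstructMatch(Chem.MolFromSmarts("[CX3](=O)[OX2H1]"))


def test_load_starter_unknown_name_lists_registry():
    mod = Module(index=0, is_loading=True, domains=[
        DomainAnnotation("AT_L", substrate_specificity="unobtainium"),
        DomainAnnotation("ACP")])
    with pytest.raises(RegistryError, match="propionyl"):
        load_starter(mod)


# ---------------------------------------------------------------------------
# condensation

@pytest.mark.parametrize("start,extender,expected", [
    ("CC(S)=O", "malonyl", "CC(=O)CC(S)=O"),
    ("CCC(S)=O", "methylmalonyl", "CCC(=O)C(C)C(S)=O"),
    ("CC(S)=O", "methoxymalonyl", "CC(=O)C(OC)C(S)=O"),
])
def test_extension_products(start, extender, expected):
    out = extend_chain(chain(start), EXT.get_unit(extender))
    assert out.smiles == canon(expected)
    assert out.tethered


def test_extension_requires_tethered_chain():
    with pytest.raises(StateError):
        extend_chain(chain("CCC(O)=O", tethered=False),
                     EXT.get_unit("malonyl"))


def test_every_registered_extender_extends(collection):
    """Each extender's fragment is chemically valid: condensation succeeds
    and adds exactly 2 backbone carbons, the new beta-ketone oxygen and the
    R' atoms."""
    base = chain("CC(S)=O")
    base_atoms = Chem.MolFromSmiles(base.smiles).GetNumAtoms()
    for name, unit in sorted(EXT.items()):
        frag = unit.alpha_substituent_smiles
        frag_atoms = (Chem.MolFromSmiles(frag).GetNumAtoms() if frag else 0)
        out = extend_chain(base, unit)
        got = Chem.MolFromSmiles(out.smiles).GetNumAtoms()
        assert got == base_atoms + 3 + frag_atoms, name
        assert count_caps(Chem.MolFromSmiles(out.smiles)) == 1


# ---------------------------------------------------------------------------
# ketoreduction and the stereo table

def test_kr_b1_on_unsubstituted_chain():
    out = kr_reduce(chain("CC(=O)CC(S)=O"), KR.get_unit("B1"))
    assert out.smiles == canon("C[C@@H](O)CC(S)=O")  # (R) by CIP


@pytest.mark.parametrize("kr_type,beta,alpha", [
    ("A1", "S", "R"), ("A2", "S", "S"), ("B1", "R", "R"), ("B2", "R", "S"),
])
def test_kr_stereo_table_on_substituted_chain(kr_type, beta, alpha):
    out = kr_reduce(chain("CCC(=O)C(C)C(S)=O"), KR.get_unit(kr_type))
    mol = Chem.MolFromSmiles(out.smiles)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    labels = {}
    for atom in mol.GetAtoms():
        if atom.HasProp("_CIPCode"):
            has_oh = any(n.GetAtomicNum() == 8 for n in atom.GetNeighbors())
            labels["beta" if has_oh else "alpha"] = atom.GetProp("_CIPCode")
    assert labels == {"beta": beta, "alpha": alpha}


def test_kr_c_types_leave_the_ketone():
    before = chain("CCC(=O)C(C)C(S)=O")
    out_c1 = kr_reduce(before, KR.get_unit("C1"))
    assert out_c1.smiles == before.smiles
    out_c2 = kr_reduce(before, KR.get_unit("C2"))
    mol = Chem.MolFromSmiles(out_c2.smiles)
    # beta-ketone retained; constitution unchanged, alpha now stereo-defined
    assert mol.HasSubstructMatch(Chem.MolFromSmarts("C(=O)[CX4]C(=O)[SX2H1]"))
    assert canon(out_c2.smiles.replace("@", "")) == before.smiles
    assert "@" in out_c2.smiles


def test_kr_u_reduces_without_stereo():
    out = kr_reduce(chain("CC(=O)CC(S)=O"), KR.get_unit("U"))
    assert out.smiles == canon("CC(O)CC(S)=O")
    assert "@" not in out.smiles


def test_kr_requires_beta_ketone():
    with pytest.raises(SubstrateError):
        kr_reduce(chain("CCCC(S)=O"), KR.get_unit("B1"))


# ---------------------------------------------------------------------------
# dehydration / enoyl reduction / methylation

def test_dehydration_gives_trans_enoyl():
    out = dehydrate(chain("CC(O)CC(S)=O"))
    assert out.smiles == canon("C/C=C/C(S)=O")


def test_dehydration_z_override():
    out = dehydrate(chain("CC(O)CC(S)=O"), geometry="Z")
    assert out.smiles == canon("C/C=C\\C(S)=O")


def test_dehydration_of_substituted_chain():
    out = dehydrate(chain("CCC(O)C(C)C(S)=O"))
    assert out.smiles == canon("CC/C=C(C)/C(S)=O")


def test_dehydration_requires_hydroxyl():
    with pytest.raises(SubstrateError):
        dehydrate(chain("CC(=O)CC(S)=O"))


def test_enoyl_reduction():
    out = enoyl_reduce(chain("C/C=C/C(S)=O"))
    assert out.smiles == canon("CCCC(S)=O")


def test_enoyl_reduction_sets_alpha_configuration():
    out = enoyl_reduce(chain("CC/C=C(C)/C(S)=O"))
    mol = Chem.MolFromSmiles(out.smiles)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    cips = [a.GetProp("_CIPCode") for a in mol.GetAtoms()
            if a.HasProp("_CIPCode")]
    assert cips == ["S"]  # default ER outcome


def test_enoyl_reduction_requires_enoyl():
    with pytest.raises(SubstrateError):
        enoyl_reduce(chain("CCCC(S)=O"))


def test_c_methylation():
    out = alpha_methylate(chain("CC(=O)CC(S)=O"), "cMT")
    assert out.smiles == canon("CC(=O)C(C)C(S)=O")


def test_c_methylation_requires_alpha_hydrogen():
    with pytest.raises(SubstrateError):
        alpha_methylate(chain("CC(=O)C(C)(C)C(S)=O"), "cMT")


def test_o_methylation():
    out = alpha_methylate(chain("CC(O)CC(S)=O"), "oMT")
    assert out.smiles == canon("COC(C)CC(S)=O")


# ---------------------------------------------------------------------------
# release

def test_hydrolysis_releases_free_acid():
    out = release_product(chain("CCCC(S)=O"), "hydrolysis")
    assert out.smiles == canon("CCCC(O)=O")
    assert not out.tethered


def test_cyclization_forms_the_expected_ring():
    # 5-hydroxy chain: lactonization onto ketide unit 2 -> 6-membered ring
    out = release_product(chain("CC(O)CC(O)CC(S)=O"), "cyclization", site=2)
    mol = Chem.MolFromSmiles(out.smiles)
    ring_sizes = [len(r) for r in mol.GetRingInfo().AtomRings()]
    assert ring_sizes == [6]
    assert count_caps(mol) == 0


def test_cyclization_without_hydroxyl_errors():
    with pytest.raises(ReleaseError):
        release_product(chain("CC(=O)CC(S)=O"), "cyclization", site=1)


def test_released_chain_cannot_be_extended_again():
    released = release_product(chain("CCCC(S)=O"), "hydrolysis")
    with pytest.raises(StateError):
        extend_chain(released, EXT.get_unit("malonyl"))


# ---------------------------------------------------------------------------
# whole-cluster invariants

def test_fixture_simulations_match_frozen_oracles(simulations):
    for cid, expected in EXPECTED_INTERMEDIATES.items():
        result = simulations[cid]
        for key, smiles in expected.items():
            if key == "product":
                assert result.product.smiles == smiles
            else:
                assert result.intermediates[int(key)].smiles == smiles


def test_emitted_smiles_are_canonical_with_one_cap(simulations):
    for result in simulations.values():
        for inter in result.intermediates:
            assert Chem.CanonSmiles(inter.smiles) == inter.smiles
            assert count_caps(Chem.MolFromSmiles(inter.smiles)) == 1
        if result.product is not None:
            assert count_caps(Chem.MolFromSmiles(result.product.smiles)) == 0


def test_backbone_conservation_across_fixtures(collection, simulations):
    """Every extension adds exactly 2 backbone carbons plus the extender's
    R' atoms (counted over all fixture simulations)."""
    ext = default_extenders()
    for cluster in collection:
        result = simulations[cluster.id]
        for prev, cur in zip(result.intermediates, result.intermediates[1:]):
            _, module = cluster.module(cur.module_index)
            at = module.domain("AT")
            frag = ext.get_unit(at.substrate_specificity).\
                alpha_substituent_smiles
            frag_atoms = (Chem.MolFromSmiles(frag).GetNumAtoms()
                          if frag else 0)
            n_prev = Chem.MolFromSmiles(prev.smiles).GetNumAtoms()
            n_cur = Chem.MolFromSmiles(cur.smiles).GetNumAtoms()
            mt_methyls = sum(1 for d in module.domains
                             if d.kind in ("cMT", "oMT") and d.active)
            dehydrations = sum(
                1 for d in module.domains if d.kind == "DH" and d.active)
            expected = (2 + frag_atoms + 1 - dehydrations + mt_methyls) \
                * module.iterations
            # +1 for the ketone oxygen retained (or hydroxyl); DH removes it
            assert n_cur - n_prev == expected, cluster.id


def test_oxidation_state_ladder():
    """For a fixed extension the beta carbon walks ketone -> hydroxyl ->
    alkene -> methylene as the cassette grows."""
    base = extend_chain(chain("CC(S)=O"), EXT.get_unit("malonyl"))
    ketone = base
    hydroxyl = kr_reduce(base, KR.get_unit("B1"))
    enoyl = dehydrate(hydroxyl)
    methylene = enoyl_reduce(enoyl)
    assert Chem.MolFromSmiles(ketone.smiles).HasSubstructMatch(
        Chem.MolFromSmarts("[CX3](=O)CC(=O)[SX2H1]"))
    assert Chem.MolFromSmiles(hydroxyl.smiles).HasSubstructMatch(
        Chem.MolFromSmarts("[CX4]([OX2H1])CC(=O)[SX2H1]"))
    assert Chem.MolFromSmiles(enoyl.smiles).HasSubstructMatch(
        Chem.MolFromSmarts("C=CC(=O)[SX2H1]"))
    assert Chem.MolFromSmiles(methylene.smiles).HasSubstructMatch(
        Chem.MolFromSmarts("[CX4;H2][CX4;H2]C(=O)[SX2H1]"))
    # each rung differs from the previous only at the beta position
    for a, b in [(ketone, hydroxyl), (hydroxyl, enoyl), (enoyl, methylene)]:
        na = Chem.MolFromSmiles(a.smiles).GetNumAtoms()
        nb = Chem.MolFromSmiles(b.smiles).GetNumAtoms()
        assert abs(na - nb) <= 1


def test_iterating_module_extends_twice(collection):
    from pksdesign.model import CorrectionRecord, apply_corrections
    cluster = next(c for c in collection if c.id == "borrelidin_fragment")
    record = CorrectionRecord(cluster.id, [
        {"op": "set_iterations", "module": 1, "n": 2}])
    iterated = apply_corrections(cluster, record)
    once = simulate_cluster(cluster).intermediates[1].smiles
    twice = simulate_cluster(iterated).intermediates[1].smiles
    def carbons(s):
        return sum(1 for a in Chem.MolFromSmiles(s).GetAtoms()
                   if a.GetAtomicNum() == 6)
    assert carbons(twice) == carbons(once) + 2  # malonyl: 2 backbone carbons


def test_substrate_error_carries_module_index(collection):
    """A DH activated where no hydroxyl can exist fails with the module
    attached."""
    from pksdesign.model import CorrectionRecord, apply_corrections
    cluster = next(c for c in collection if c.id == "borrelidin_fragment")
    record = CorrectionRecord(cluster.id, [
        {"op": "set_domain_activity", "module": 1, "domain": "KR",
         "active": False},
        {"op": "set_domain_activity", "module": 2, "domain": "KR",
         "active": False}])
    broken = apply_corrections(cluster, record)
    with pytest.raises(SubstrateError, match="module 2"):
        simulate_cluster(broken)


def test_truncated_cluster_simulates_to_truncation_point(collection):
    import json
    from pksdesign.model import parse_cluster_json, write_cluster_json
    doc = json.loads(write_cluster_json(collection[0]))
    doc["subunits"][2]["modules"][0]["domains"][0]["kind"] = "WEIRD"
    truncated = parse_cluster_json(json.dumps(doc))
    result = simulate_cluster(truncated)
    assert truncated.truncated
    assert len(result.intermediates) == 2  # loading + module 1 only
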