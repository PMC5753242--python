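"""Retro-biosynthetic decomposition, donor ranking and chimera simulation."""

import pytest
from rdkit import Chem

from pksdesign.chimera import (ChimeraPlan, apply_exchanges, design,
                               diff_to_exchanges, find_parent, match_starter,
                               rank_donors, retro_parse_terminal_unit,
                               simulate_chimera)
from pksdesign.errors import DecompositionError
from pksdesign.fixtures import ADIPIC_ACID

STEREOLESS = lambda s: Chem.CanonSmiles(s.replace("@", "").replace("/", "")
                                        .replace("\\", ""))


def _bor_module(collection):
    bor = next(c for c in collection if c.id == "borrelidin_fragment")
    return bor, bor.module(1)


# ---------------------------------------------------------------------------
# retro-parse

def test_retro_parse_adipic_acid():
    unit = retro_parse_terminal_unit(ADIPIC_ACID)
    assert unit.extender_name == "malonyl"
    assert unit.beta_state == "methylene"
    assert match_starter(unit.precursor_acyl_smiles) == "succinyl"


@pytest.mark.parametrize("target,extender,beta", [
    ("CCCC(C)C(=O)O", "methylmalonyl", "methylene"),
    ("CCC(O)CC(=O)O", "malonyl", "hydroxyl"),
    ("CC/C=C/C(=O)O", "malonyl", "enoyl"),
    ("CCC(=O)CC(=O)O", "malonyl", "ketone"),
    ("CCC(=O)C(CC)C(=O)O", "ethylmalonyl", "ketone"),
])
def test_retro_parse_classifies_terminal_units(target, extender, beta):
    unit = retro_parse_terminal_unit(target)
    assert unit.extender_name == extender
    assert unit.beta_state == beta


def test_retro_parse_rejects_cyclic_and_non_acid_targets():
    with pytest.raises(DecompositionError):
        retro_parse_terminal_unit("C1CCCCC1O")  # no carboxyl; cyclic
    with pytest.raises(DecompositionError):
        retro_parse_terminal_unit("CCO")  # no carboxylic acid


# ---------------------------------------------------------------------------
# decomposition into exchanges

def test_adipic_vs_borrelidin_module_one(collection, simulations):
    _, (_, module) = _bor_module(collection)
    parent_inter = simulations["borrelidin_fragment"].intermediates[1]
    exchanges = diff_to_exchanges(ADIPIC_ACID, parent_inter, module)
    kinds = [ex.exchange_kind for ex in exchanges]
    assert kinds == ["reductive_loop_swap", "append_TE"]
    loop = exchanges[0]
    assert loop.required_cassette == {"KR", "DH", "ER"}
    assert loop.required_at_substrate == "malonyl"
    assert exchanges[1].te_mode == "hydrolysis"


def test_matching_target_needs_no_exchanges(collection, simulations):
    toy = next(c for c in collection if c.id == "toy_triketide")
    _, module = toy.module(2)
    parent_inter = simulations["toy_triketide"].intermediates[2]
    target = simulations["toy_triketide"].product.smiles
    assert diff_to_exchanges(target, parent_inter, module) == []


def test_alpha_methyl_difference_emits_at_swap(collection, simulations):
    _, (_, module) = _bor_module(collection)  # malonyl AT, KR-only
    parent_inter = simulations["borrelidin_fragment"].intermediates[1]
    # target: alpha-methyl, beta-hydroxyl -> AT swap only (plus TE)
    target = "CCC(O)C(C)C(=O)O"
    exchanges = diff_to_exchanges(target, parent_inter, module)
    kinds = [ex.exchange_kind for ex in exchanges]
    assert kinds == ["AT_swap", "append_TE"]
    assert exchanges[0].required_at_substrate == "methylmalonyl"


def test_single_stage_difference_emits_single_domain_swap(collection,
                                                          simulations):
    bor = next(c for c in collection if c.id == "borrelidin_fragment")
    _, module2 = bor.module(2)  # malonyl, KR+DH active
    parent_inter = simulations["borrelidin_fragment"].intermediates[2]
    target = "CCCC(O)CC(=O)O"  # wants hydroxyl: only DH differs
    exchanges = diff_to_exchanges(target, parent_inter, module2)
    kinds = [ex.exchange_kind for ex in exchanges]
    assert kinds == ["DH_swap", "append_TE"]


# ---------------------------------------------------------------------------
# donor ranking

def test_loop_swap_donors_are_the_two_standalone_full_cassette_modules(
        collection, simulations):
    bor, (subunit, module) = _bor_module(collection)
    parent_inter = simulations["borrelidin_fragment"].intermediates[1]
    loop = diff_to_exchanges(ADIPIC_ACID, parent_inter, module)[0]
    donors = rank_donors(loop, subunit.sequence, collection,
                         require_standalone=True)
    assert [(d.cluster_id, d.subunit_name) for d in donors] == [
        ("indanomycin_fragment", "IdmO"),
        ("spinosyn_fragment", "SpnB"),
    ]
    assert donors[0].bit_score > donors[1].bit_score


def test_dh_swap_donor_is_highest_bit_score_active_dh(collection,
                                                      simulations):
    bor, (subunit, module2) = _bor_module(collection)
    _, module2 = bor.module(2)
    parent_inter = simulations["borrelidin_fragment"].intermediates[2]
    ex = diff_to_exchanges("CC/C=C/CC(O)CC(=O)O", parent_inter,
                           bor.module(1)[1])
    # construct a DH_swap directly for the donor query
    from pksdesign.chimera import DomainExchange
    dh_swap = DomainExchange("DH_swap", 1, required_cassette=frozenset({"DH"}))
    donors = rank_donors(dh_swap, subunit.sequence, collection)
    assert donors, "expected at least one active-DH donor"
    top = donors[0]
    assert "DH" in {k for s in top.signatures.values() for k in s.cassette}
    assert top.bit_score == max(d.bit_score for d in donors)
    # with the fixture mutation distances, the sibling subunit BorA3 wins
    assert top.subunit_name == "BorA3"


def test_no_qualifying_donor_returns_empty(collection):
    from pksdesign.chimera import DomainExchange
    bor, (subunit, _) = _bor_module(collection)
    ex = DomainExchange("reductive_loop_swap", 1,
                        required_at_substrate="ethylmalonyl",
                        required_cassette=frozenset({"KR", "DH", "ER"}))
    assert rank_donors(ex, subunit.sequence, collection) == []


# ---------------------------------------------------------------------------
# grafting + simulation

def test_design_produces_adipic_acid(collection):
    plan = design(ADIPIC_ACID, collection)
    assert plan.parent_cluster_id == "borrelidin_fragment"
    assert plan.parent_module_index == 1
    assert plan.starter_override == "succinyl"
    assert plan.predicted_product is not None
    assert Chem.CanonSmiles(plan.predicted_product.smiles) == \
        Chem.CanonSmiles(ADIPIC_ACID)
    assert plan.matches_target is True


def test_zero_exchange_plan_reproduces_parent_product(collection,
                                                      simulations):
    plan = ChimeraPlan(
        target=simulations["toy_triketide"].product.smiles,
        parent_cluster_id="toy_triketide", parent_module_index=2,
        parent_score=1.0, exchanges=[])
    product = simulate_chimera(plan, collection)
    assert product.smiles == simulations["toy_triketide"].product.smiles


def test_dh_graft_without_er_gives_enoyl_acid(collection):
    from pksdesign.chimera import DomainExchange
    plan = ChimeraPlan(
        target="ignored", parent_cluster_id="borrelidin_fragment",
        parent_module_index=1, parent_score=1.0,
        exchanges=[
            DomainExchange("reductive_loop_swap", 1,
                           required_cassette=frozenset({"KR", "DH"})),
            DomainExchange("append_TE", 1, te_mode="hydrolysis"),
        ])
    product = simulate_chimera(plan, collection)
    mol = Chem.MolFromSmiles(product.smiles)
    assert mol.HasSubstructMatch(
        Chem.MolFromSmarts("C=CC(=O)[OX2H1]"))
    assert not product.tethered


def test_exchange_minimality_for_adipic_design(collection):
    """Dropping any planned exchange no longer yields the target."""
    plan = design(ADIPIC_ACID, collection)
    assert plan.matches_target
    for skip in range(len(plan.exchanges)):
        reduced = ChimeraPlan(
            target=plan.target,
            parent_cluster_id=plan.parent_cluster_id,
            parent_module_index=plan.parent_module_index,
            parent_score=plan.parent_score,
            exchanges=[ex for i, ex in enumerate(plan.exchanges)
                       if i != skip],
            donors={j: d for j, (i, d) in enumerate(
                (i, d) for i, d in plan.donors.items() if i != skip)},
            starter_override=plan.starter_override)
        product = simulate_chimera(reduced, collection)
        assert product is None or STEREOLESS(product.smiles) != \
            STEREOLESS(plan.target)


def test_donor_lists_are_subsets_of_sequence_search(collection, simulations):
    from pksdesign.sequence_search import search_sequences
    bor, (subunit, module) = _bor_module(collection)
    parent_inter = simulations["borrelidin_fragment"].intermediates[1]
    loop = diff_to_exchanges(ADIPIC_ACID, parent_inter, module)[0]
    donors = rank_donors(loop, subunit.sequence, collection,
                         require_standalone=True)
    all_hits = search_sequences(subunit.sequence, collection)
    order = [(h.cluster_id, h.subunit_name) for h in all_hits]
    donor_keys = [(d.cluster_id, d.subunit_name) for d in donors]
    assert set(donor_keys) <= set(order)
    assert sorted(donor_keys, key=order.index) == donor_keys
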