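"""Core data-model behavior: formulas, GPRs, balance audits, editing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterogem.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    add_boundary_reaction,
    check_charge_balance,
    check_mass_balance,
    format_formula,
    gpr_genes,
    merge_metabolites,
    model_stats,
    parse_formula,
    parse_gpr,
)
from heterogem.model import gpr_to_string


# ---------------------------------------------------------------------------
# formulas


@pytest.mark.parametrize(
    "text,expected",
    [
        ("H2O", {"H": 2, "O": 1}),
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
        ("CHR", {"C": 1, "H": 1, "R": 1}),  # pseudo-element kept opaque
        ("X", {"X": 1}),
        ("Fe2S2", {"Fe": 2, "S": 2}),
    ],
)
def test_formula_parsing(text, expected):
    assert parse_formula(text) == expected


def test_formula_rejects_garbage():
    with pytest.raises(ValueError):
        parse_formula("2H")
    with pytest.raises(ValueError):
        parse_formula("C6-H12")


@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe", "R", "X"]),
        st.integers(min_value=1, max_value=99),
        min_size=1,
        max_size=6,
    )
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_formula_roundtrip(counts):
    assert parse_formula(format_formula(counts)) == counts


# ---------------------------------------------------------------------------
# GPR rules


@pytest.mark.parametrize(
    "rule,genes",
    [
        ("g1", {"g1"}),
        ("g1 and g2", {"g1", "g2"}),
        ("(g1 and g2) or g3", {"g1", "g2", "g3"}),
        ("g1 or g2 and g3", {"g1", "g2", "g3"}),  # and binds tighter
    ],
)
def test_gpr_parse_and_genes(rule, genes):
    tree = parse_gpr(rule)
    assert gpr_genes(tree) == genes
    assert gpr_genes(parse_gpr(gpr_to_string(tree))) == genes


def test_gpr_precedence():
    assert parse_gpr("g1 or g2 and g3") == ("or", "g1", ("and", "g2", "g3"))


def test_gpr_rejects_malformed():
    with pytest.raises(ValueError):
        parse_gpr("(g1 and")
    with pytest.raises(ValueError):
        parse_gpr("and g1")


# ---------------------------------------------------------------------------
# balance audits (hand-computed element arithmetic)


@pytest.fixture
def hexokinase_table():
    return {
        "glc__D_c": Metabolite("glc__D_c", "glucose", "c",
                               parse_formula("C6H12O6"), 0),
        "atp_c": Metabolite("atp_c", "ATP", "c",
                            parse_formula("C10H12N5O13P3"), -4),
        "g6p_c": Metabolite("g6p_c", "G6P", "c", parse_formula("C6H11O9P"), -2),
        "adp_c": Metabolite("adp_c", "ADP", "c",
                            parse_formula("C10H12N5O10P2"), -3),
        "h_c": Metabolite("h_c", "proton", "c", parse_formula("H"), 1),
        "h2o_c": Metabolite("h2o_c", "water", "c", parse_formula("H2O"), 0),
        "h2o_e": Metabolite("h2o_e", "water", "e", parse_formula("H2O"), 0),
    }


def test_water_transport_balanced(hexokinase_table):
    rxn = Reaction("H2Ot", "", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000)
    assert check_mass_balance(rxn, hexokinase_table) == {}
    assert check_charge_balance(rxn, hexokinase_table) == 0.0


def test_hexokinase_balanced(hexokinase_table):
    stoich = {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}
    rxn = Reaction("HEX1", "", stoich, 0, 1000)
    assert check_mass_balance(rxn, hexokinase_table) == {}
    assert check_charge_balance(rxn, hexokinase_table) == 0.0


def test_hexokinase_missing_proton(hexokinase_table):
    stoich = {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}
    rxn = Reaction("HEX1", "", stoich, 0, 1000)
    assert check_mass_balance(rxn, hexokinase_table) == {"H": -1}
    assert check_charge_balance(rxn, hexokinase_table) == -1


def test_missing_formula_is_unauditable_not_balanced(hexokinase_table):
    table = dict(hexokinase_table)
    table["mystery_c"] = Metabolite("mystery_c", "?", "c", None, None)
    rxn = Reaction("R1", "", {"glc__D_c": -1, "mystery_c": 1}, 0, 1000)
    assert "unauditable" in check_mass_balance(rxn, table)
    assert check_charge_balance(rxn, table) is None


def test_pseudo_reactions_exempt(hexokinase_table):
    rxn = Reaction("EX_h2o_e", "", {"h2o_e": -1}, -1000, 1000, kind="exchange")
    assert check_mass_balance(rxn, hexokinase_table) == {"exempt": 0.0}
    bio = Reaction("BIOMASS", "", {"glc__D_c": -30}, 0, 1000, kind="biomass")
    assert "exempt" in check_mass_balance(bio, hexokinase_table)


# ---------------------------------------------------------------------------
# merging and boundaries


def _two_route_model():
    m = MetabolicModel("dup")
    for mid in ("a_c", "a2_c", "b_c"):
        m.add_metabolite(Metabolite(mid, mid, "c", parse_formula("CH2O"), 0))
    m.add_reaction(Reaction("R1", "", {"a_c": -1, "b_c": 1}, 0, 1000))
    m.add_reaction(Reaction("R2", "", {"a2_c": -1, "b_c": 1}, 0, 1000))
    return m


def test_merge_collapses_duplicate_reactions():
    m = _two_route_model()
    merge_metabolites(m, "a_c", "a2_c")
    assert "a2_c" not in m.metabolites
    assert len(m.reactions) == 1
    (rxn,) = m.reactions.values()
    assert rxn.stoichiometry == {"a_c": -1, "b_c": 1}


def test_merge_retains_unique_reaction():
    # the duplicate metabolite has one reaction of its own that must survive
    m = _two_route_model()
    m.add_metabolite(Metabolite("c_c", "c", "c", parse_formula("CH2O"), 0))
    m.add_reaction(Reaction("R3", "", {"a2_c": -1, "c_c": 1}, 0, 1000))
    merge_metabolites(m, "a_c", "a2_c")
    assert set(m.reactions) == {"R1", "R3"}
    assert m.reactions["R3"].stoichiometry == {"a_c": -1, "c_c": 1}


def test_merge_identity_is_noop():
    m = _two_route_model()
    merge_metabolites(m, "a_c", "a_c")
    assert set(m.reactions) == {"R1", "R2"}


def test_merge_across_compartments_fails():
    m = _two_route_model()
    m.add_metabolite(Metabolite("a_e", "a", "e", parse_formula("CH2O"), 0))
    with pytest.raises(ValueError):
        merge_metabolites(m, "a_c", "a_e")


def test_merge_preserves_balance_of_untouched_reactions(core_model):
    m = core_model.copy()
    m.add_metabolite(
        Metabolite("pyr2_c", "pyruvate (dup)", "c", parse_formula("C3H3O3"), -1)
    )
    m.add_reaction(Reaction("RX", "", {"pyr2_c": -1, "lac__L_c": 1,
                                       "nadh_c": -1, "h_c": -1, "nad_c": 1},
                            0, 1000))
    before = {
        rid: check_mass_balance(r, m.metabolites)
        for rid, r in m.reactions.items()
        if "pyr2_c" not in r.stoichiometry
    }
    merge_metabolites(m, "pyr_c", "pyr2_c")
    for rid, audit in before.items():
        if rid in m.reactions:
            assert check_mass_balance(m.reactions[rid], m.metabolites) == audit


def test_add_demand_and_exchange():
    m = _two_route_model()
    rxn = add_boundary_reaction(m, "b_c", "demand")
    assert rxn.id == "DM_b_c"
    assert rxn.stoichiometry == {"b_c": -1.0}
    assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)
    m.add_metabolite(Metabolite("fe2_e", "Fe2+", "e", parse_formula("Fe"), 2))
    ex = add_boundary_reaction(m, "fe2_e", "exchange")
    assert ex.id == "EX_fe2_e"
    assert (ex.lower_bound, ex.upper_bound) == (-1000.0, 1000.0)


def test_exchange_for_cytosolic_metabolite_fails():
    m = _two_route_model()
    with pytest.raises(ValueError):
        add_boundary_reaction(m, "a_c", "exchange")


def test_duplicate_boundary_fails():
    m = _two_route_model()
    add_boundary_reaction(m, "b_c", "demand")
    with pytest.raises(ValueError):
        add_boundary_reaction(m, "b_c", "demand")


# ---------------------------------------------------------------------------
# stats


def test_model_stats_empty():
    assert model_stats(MetabolicModel("empty")) == {
        "genes": 0, "reactions": 0, "reactions_without_gpr": 0, "metabolites": 0,
    }


def test_model_stats_counts_gprless():
    m = _two_route_model()
    m.reactions["R1"].gpr = parse_gpr("g1 and g2")
    stats = model_stats(m)
    assert stats["reactions"] == 2
    assert stats["reactions_without_gpr"] == 1
    assert stats["genes"] == 2


def test_duplicate_ids_rejected():
    m = _two_route_model()
    with pytest.raises(ValueError):
        m.add_reaction(Reaction("R1", "", {"a_c": -1, "b_c": 1}, 0, 1000))
    with pytest.raises(ValueError):
        m.add_metabolite(Metabolite("a_c", "a", "c"))
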