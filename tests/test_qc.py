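"""Curation diagnostics: duplicates, dead ends, loops, gene sets, report."""

import numpy as np
import pytest
from scipy.linalg import null_space

import heterogem as hg
from heterogem.lp import _build_system
from heterogem.model import MetabolicModel, Metabolite, Reaction, parse_formula
from heterogem.qc import (
    compare_gene_sets,
    detect_dead_ends,
    detect_duplicate_metabolites,
    detect_duplicate_reactions,
    detect_loops,
    normalize_name,
    qc_report,
)


# ---------------------------------------------------------------------------
# duplicate metabolites


def test_stereo_prefix_normalization():
    assert normalize_name("S-acetoin") == normalize_name("(S)-acetoin")
    assert normalize_name("S,S-2,3-butanediol") == normalize_name(
        "(S,S)-2,3-butanediol"
    )
    assert normalize_name("acetoin") != normalize_name("butanediol")


def test_duplicate_metabolites_grouped_by_name_and_chemistry():
    m = MetabolicModel("dups")
    m.add_metabolite(Metabolite("actn_c", "S-acetoin", "c",
                                parse_formula("C4H8O2"), 0))
    m.add_metabolite(Metabolite("actn2_c", "(S)-acetoin", "c",
                                parse_formula("C4H8O2"), 0))
    m.add_metabolite(Metabolite("actn_e", "S-acetoin", "e",
                                parse_formula("C4H8O2"), 0))  # other compartment
    m.add_metabolite(Metabolite("btd_c", "butanediol", "c",
                                parse_formula("C4H8O2"), 0))  # other name
    m.add_metabolite(Metabolite("myst_c", "S-acetoin", "c", None, None))  # no formula
    assert detect_duplicate_metabolites(m) == [["actn2_c", "actn_c"]]


def test_duplicate_metabolites_empty_model():
    assert detect_duplicate_metabolites(MetabolicModel("e")) == []


# ---------------------------------------------------------------------------
# dead ends


def _ab_model():
    m = MetabolicModel("deadends")
    for mid in ("a_c", "b_c", "c_c", "c_e"):
        comp = "e" if mid.endswith("_e") else "c"
        m.add_metabolite(Metabolite(mid, mid, comp, parse_formula("CH2O"), 0))
    m.add_reaction(Reaction("AB", "", {"a_c": -1, "b_c": 1}, 0, 1000))
    return m


def test_dead_ends_simple_chain():
    m = _ab_model()
    assert detect_dead_ends(m) == ["a_c", "b_c"]


def test_dead_ends_resolved_by_reversible_link_and_exchange():
    m = _ab_model()
    m.add_reaction(Reaction("BC", "", {"b_c": -1, "c_c": 1}, -1000, 1000))
    m.add_reaction(Reaction("Ct", "", {"c_c": -1, "c_e": 1}, -1000, 1000))
    m.add_reaction(Reaction("EX_c_e", "", {"c_e": -1}, -1000, 1000,
                            kind="exchange"))
    # a_c still lacks a producer; everything downstream is covered
    assert detect_dead_ends(m) == ["a_c"]
    m.add_reaction(Reaction("EX_a", "", {"a_c": -1}, -1000, 1000, kind="sink"))
    assert detect_dead_ends(m) == []


def test_acetolactate_dead_end_resolved_by_consumer(core_model):
    # removing the acetolactate consumer recreates the dead end;
    # the shipped core (with the consumer present) has none
    m = core_model.copy()
    m.remove_reaction("ACLDC")
    assert "alac__S_c" in detect_dead_ends(m)
    assert "alac__S_c" not in detect_dead_ends(core_model)


# ---------------------------------------------------------------------------
# loops


def test_loop_fixture_flags_exactly_the_cycle():
    fixture = hg.make_loop_fixture()
    assert detect_loops(fixture) == ["CYCAB", "CYCBC", "CYCCA"]


def test_loop_broken_by_blocking_one_edge():
    fixture = hg.make_loop_fixture()
    fixture.reactions["CYCCA"].lower_bound = 0.0
    fixture.reactions["CYCCA"].upper_bound = 0.0
    assert detect_loops(fixture) == []


def test_irreversible_consistent_cycle_still_flagged():
    fixture = hg.make_loop_fixture()
    for rid in ("CYCAB", "CYCBC", "CYCCA"):
        fixture.reactions[rid].lower_bound = 0.0  # all forward, same orientation
    assert detect_loops(fixture) == ["CYCAB", "CYCBC", "CYCCA"]


def test_loops_invariant_to_medium(core_model):
    rich = hg.apply_medium(core_model, hg.cdm_medium())
    starved = hg.apply_medium(core_model, hg.MediumSpec(uptake={}))
    assert detect_loops(rich) == detect_loops(starved) == detect_loops(core_model)


def test_loop_reactions_lie_in_boundary_free_null_space():
    # remove boundary reactions entirely: any remaining null-space vector is
    # a pure internal circulation, and must coincide with the flagged set
    fixture = hg.make_loop_fixture()
    flagged = set(detect_loops(fixture))
    internal = fixture.copy()
    for rxn in list(internal.reactions.values()):
        if rxn.boundary:
            internal.remove_reaction(rxn.id)
    rxn_ids, S, _ = _build_system(internal)
    ns = null_space(S.toarray())
    assert ns.shape[1] >= 1
    support = set()
    for k in range(ns.shape[1]):
        vec = ns[:, k]
        support |= {rid for j, rid in enumerate(rxn_ids) if abs(vec[j]) > 1e-9}
    assert support == flagged


# ---------------------------------------------------------------------------
# gene sets


def test_gene_sets_identical_models(core_model):
    comp = compare_gene_sets({"a": core_model, "b": core_model})
    assert set(comp.regions) == {("a", "b")}
    assert comp.unique == {"a": [], "b": []}


def test_gene_sets_regions():
    comp = compare_gene_sets({"m1": {"a", "b"}, "m2": {"b", "c"}})
    assert comp.regions == {("m1",): 1, ("m1", "m2"): 1, ("m2",): 1}
    assert comp.unique["m1"] == ["a"]


def test_gene_sets_mapping_drops_unmapped():
    mapping = {"old1": "new1", "old2": "new2", "old3": "new3"}
    comp = compare_gene_sets(
        {"m": {"old1", "old2", "ghost_a", "ghost_b"}, "n": {"old3"}},
        mapping=mapping,
    )
    assert comp.dropped == {"m": 2, "n": 0}
    assert comp.regions == {("m",): 2, ("n",): 1}


def test_gene_sets_duplicate_names_rejected():
    with pytest.raises(ValueError):
        compare_gene_sets([("m", {"a"}), ("m", {"b"})])


# ---------------------------------------------------------------------------
# consolidated report


def test_qc_report_clean_core(core_qc):
    assert core_qc.clean()
    assert core_qc.mass_unbalanced == []
    assert core_qc.charge_unbalanced == []
    assert core_qc.unauditable == []


def test_qc_report_counts_single_broken_reaction(core_model):
    m = core_model.copy()
    m.add_reaction(Reaction("BAD", "", {"pyr_c": -1, "ac_c": 1}, 0, 1000))
    report = qc_report(m, check_loops=False)
    assert report.mass_unbalanced == ["BAD"]


def test_qc_report_empty_model():
    report = qc_report(MetabolicModel("empty"))
    assert all(v == 0 for v in report.counts().values())


def test_qc_report_json_counts_match_lists(tmp_path, core_qc):
    import json

    text = core_qc.to_json(tmp_path / "qc.json")
    payload = json.loads(text)
    for key, count in payload["counts"].items():
        assert count == len(payload[key])


def test_duplicate_reactions_detected_after_float_noise():
    m = MetabolicModel("noise")
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid, mid, "c", parse_formula("CH2O"), 0))
    m.add_reaction(Reaction("R1", "", {"a_c": -1.0, "b_c": 2.0}, 0, 1000))
    m.add_reaction(Reaction("R2", "", {"a_c": -1.0 - 1e-13, "b_c": 2.0 + 1e-13},
                            0, 1000))
    assert detect_duplicate_reactions(m) == [("R1", "R2")]
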