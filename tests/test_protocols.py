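"""Named simulation protocols: media, sweeps, turnover, sensitivity, swaps."""

import logging

import pytest

import heterogem as hg
from heterogem import CoreConfig
from heterogem.model import MetabolicModel, Metabolite, Reaction, parse_formula
from heterogem.protocols import cofactor_turnover


# ---------------------------------------------------------------------------
# medium application


def test_apply_medium_caps_and_closures(core_model):
    m = hg.apply_medium(core_model, hg.cdm_medium())
    assert m.reactions["EX_glc__D_e"].lower_bound == -25.0
    assert m.reactions["EX_arg__L_e"].lower_bound == -0.2
    # absent from the medium: uptake closed, secretion still open
    assert m.reactions["EX_lac__L_e"].lower_bound == 0.0
    assert m.reactions["EX_lac__L_e"].upper_bound == 1000.0
    assert m.reactions["EX_o2_e"].lower_bound == 0.0
    # the input model is untouched
    assert core_model.reactions["EX_glc__D_e"].lower_bound == -1000.0


def test_apply_medium_reports_missing_exchanges(core_model, caplog):
    spec = hg.MediumSpec(uptake={"EX_glc__D_e": 25.0, "EX_unobtainium_e": 1.0})
    with caplog.at_level(logging.WARNING, logger="heterogem.protocols"):
        hg.apply_medium(core_model, spec)
    assert "EX_unobtainium_e" in caplog.text


# ---------------------------------------------------------------------------
# sweeps


@pytest.fixture(scope="module")
def cdm_core():
    return hg.apply_medium(hg.build_core_model(), hg.cdm_medium())


def test_glucose_sweep_shape_and_monotonicity(cdm_core):
    result = hg.substrate_sweep(cdm_core, "EX_glc__D_e", range(0, 26))
    assert len(result.rows) == 26
    growths = [r["growth"] for r in result.rows if r["status"] == "optimal"]
    assert all(b >= a - 1e-9 for a, b in zip(growths, growths[1:]))
    df = result.to_dataframe()
    assert len(df) == 26


def test_sweep_zero_point_infeasible_with_maintenance():
    # at zero glucose the 0.51 maintenance floor cannot be met from the
    # 0.2 arginine allowance alone
    m = hg.apply_medium(hg.build_core_model(), hg.cdm_medium())
    result = hg.substrate_sweep(m, "EX_glc__D_e", [0.0, 5.0])
    assert result.rows[0]["status"] == "infeasible"
    assert "growth" not in result.rows[0]
    assert result.rows[1]["status"] == "optimal"


def test_sweep_grid_must_increase(cdm_core):
    with pytest.raises(ValueError):
        hg.substrate_sweep(cdm_core, "EX_glc__D_e", [5.0, 5.0])


def test_sweep_pfba_point_inside_fva_envelope(cdm_core):
    result = hg.substrate_sweep(cdm_core, "EX_glc__D_e", [5.0, 15.0, 25.0])
    for row in result.rows:
        assert row["status"] == "optimal"
        for exch, flux in row["pfba"].items():
            lo, hi = row["fva"][exch]
            assert lo - 1e-5 <= flux <= hi + 1e-5


def test_oxygen_sweep_ethanol_acetate_shift(cdm_core):
    result = hg.oxygen_sweep(cdm_core, glucose_cap=10.0, o2_grid=range(0, 11))
    rows = [r for r in result.rows if r["status"] == "optimal"]
    assert len(rows) == 11
    etoh_max = [r["fva"]["EX_etoh_e"][1] for r in rows]
    ac_max = [r["fva"]["EX_ac_e"][1] for r in rows]
    assert all(b <= a + 1e-6 for a, b in zip(etoh_max, etoh_max[1:]))
    assert all(b >= a - 1e-6 for a, b in zip(ac_max, ac_max[1:]))


def test_aerobic_growth_exceeds_anaerobic(cdm_core):
    anaerobic = hg.fba(cdm_core).objective_value
    aerobic = cdm_core.copy()
    aerobic.reactions["EX_o2_e"].lower_bound = -10.0
    assert hg.fba(aerobic).objective_value > anaerobic + 1e-6


# ---------------------------------------------------------------------------
# cofactor turnover


def test_turnover_counts_production_side():
    m = MetabolicModel("gapd")
    for mid, f, q in [("g3p_c", "C3H5O6P", -2), ("x_c", "C3H5O6P", -2),
                      ("nad_c", "C21H26N7O14P2", -1),
                      ("nadh_c", "C21H27N7O14P2", -2),
                      ("nadp_c", "C21H25N7O17P3", -3),
                      ("nadph_c", "C21H26N7O17P3", -4)]:
        m.add_metabolite(Metabolite(mid, mid, "c", parse_formula(f), q))
    m.add_reaction(Reaction("GAPD", "", {"g3p_c": -1, "nad_c": -1,
                                         "x_c": 1, "nadh_c": 1}, -1000, 1000))
    sol = hg.FluxSolution(status="optimal", objective_value=0.0,
                          fluxes={"GAPD": 2.0})
    t = cofactor_turnover(m, sol)
    assert (t.nadh_production, t.nadph_production) == (2.0, 0.0)
    assert t.ratio is None  # undefined when NADPH total is zero


def test_turnover_reversed_flux_counts_actual_side():
    m = MetabolicModel("rev")
    for mid in ("a_c", "nadh_c", "nad_c", "nadph_c", "nadp_c", "b_c"):
        m.add_metabolite(Metabolite(mid, mid, "c"))
    # written as NADH-consuming; run backwards it produces NADH
    m.add_reaction(Reaction("R", "", {"a_c": -1, "nadh_c": -1,
                                      "b_c": 1, "nad_c": 1}, -1000, 1000))
    backward = hg.FluxSolution(status="optimal", fluxes={"R": -3.0})
    t = cofactor_turnover(m, backward)
    assert t.nadh_production == 3.0


def test_turnover_zero_flux_vector(core_model):
    sol = hg.FluxSolution(status="optimal",
                          fluxes={r: 0.0 for r in core_model.reactions})
    t = cofactor_turnover(core_model, sol)
    assert (t.nadh_production, t.nadph_production) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# shunt comparison


@pytest.fixture(scope="module")
def comparison_table():
    # strict-NADH policy: the redox regime in which the shunt is decisive
    cfg = CoreConfig(include_nadtrhd=True, ngam_lb=0.0,
                     ethanol_branch="strict_NADH")
    model = hg.apply_medium(hg.build_core_model(cfg), hg.cdm_medium(),
                            inplace=True)
    return hg.shunt_comparison(model)


def test_shunt_comparison_growth_ordering(comparison_table):
    t = comparison_table.set_index("variant")
    assert t.loc["shunt", "growth"] > t.loc["baseline", "growth"]
    assert t.loc["nadtrhd", "growth"] > t.loc["baseline", "growth"]


def test_shunt_fraction_in_unit_interval(comparison_table):
    t = comparison_table.set_index("variant")
    for variant in ("baseline", "nadtrhd", "shunt", "both"):
        assert 0.0 - 1e-9 <= t.loc[variant, "shunt_fraction"] <= 1.0 + 1e-9
    assert t.loc["shunt", "shunt_fraction"] > 0.5  # shunt is the primary route


def test_nadtrhd_shifts_turnover_toward_nadh(comparison_table):
    t = comparison_table.set_index("variant")
    base_ratio = t.loc["baseline", "nadh_production"] / t.loc[
        "baseline", "nadph_production"]
    trhd_ratio = t.loc["nadtrhd", "nadh_production"] / t.loc[
        "nadtrhd", "nadph_production"]
    assert trhd_ratio > base_ratio


def test_shunt_comparison_skips_absent_nadtrhd():
    model = hg.apply_medium(hg.build_core_model(CoreConfig(ngam_lb=0.0)),
                            hg.cdm_medium(), inplace=True)
    table = hg.shunt_comparison(model).set_index("variant")
    assert table.loc["nadtrhd", "status"] == "skipped"
    assert table.loc["shunt", "status"] == "optimal"


# ---------------------------------------------------------------------------
# biomass sensitivity, NGAM, swaps


@pytest.fixture(scope="module")
def sensitivity_result(cdm_core):
    spec = hg.make_biomass_spec("default")
    return hg.biomass_sensitivity(cdm_core, spec, factors=(0.5, 1.0, 1.5))


def test_sensitivity_factor_one_is_exactly_baseline(sensitivity_result):
    ones = [r for r in sensitivity_result.rows if r["factor"] == 1.0]
    assert ones
    for row in ones:
        assert row["percent_change"] == 0.0
        assert row["growth"] == sensitivity_result.baseline_growth


def test_sensitivity_increase_never_raises_growth(sensitivity_result):
    for row in sensitivity_result.rows:
        if row["factor"] == 1.5 and row["status"] == "optimal":
            assert row["percent_change"] <= 1e-6, row


def test_sensitivity_is_side_effect_free(cdm_core):
    import io as _io

    def snapshot(m):
        buf = _io.StringIO()
        for rid in sorted(m.reactions):
            r = m.reactions[rid]
            buf.write(f"{rid}{sorted(r.stoichiometry.items())}"
                      f"{r.lower_bound}{r.upper_bound}\n")
        return buf.getvalue()

    before = snapshot(cdm_core)
    hg.biomass_sensitivity(cdm_core, hg.make_biomass_spec("default"),
                           factors=(0.5,))
    assert snapshot(cdm_core) == before


def test_atp_group_scaling_keeps_quartet_matched(cdm_core):
    # re-run the scaling by hand and audit the biomass reaction
    spec = hg.make_biomass_spec("default")
    work = cdm_core.copy()
    rxn = work.reactions["BIOMASS"]
    members = [c.metabolite for c in spec.components
               if c.group == "atp_hydrolysis"]
    for met in members:
        rxn.stoichiometry[met] *= 1.5
    coeffs = {m: abs(rxn.stoichiometry[m]) for m in members}
    assert len(set(round(v, 9) for v in coeffs.values())) == 1
    assert rxn.stoichiometry["atp_c"] < 0 < rxn.stoichiometry["adp_c"]


def test_ngam_growth_non_increasing(cdm_core):
    table = hg.ngam_sensitivity(cdm_core, levels=(0.0, 0.36, 0.51))
    assert list(table["ngam_lb"]) == [0.0, 0.36, 0.51]
    growths = list(table["growth"])
    assert all(b <= a + 1e-9 for a, b in zip(growths, growths[1:]))
    assert table.loc[0, "percent_change"] == 0.0


def test_biomass_swap_roundtrip_and_growth_difference(cdm_core):
    default = hg.make_biomass_spec("default")
    variant = hg.make_biomass_spec("swap_variant_A")
    swapped = hg.biomass_swap(cdm_core, variant)
    restored = hg.biomass_swap(swapped, default)
    assert restored.reactions["BIOMASS"].stoichiometry == pytest.approx(
        cdm_core.reactions["BIOMASS"].stoichiometry
    )
    assert restored.reactions["PROTEINS"].stoichiometry == pytest.approx(
        cdm_core.reactions["PROTEINS"].stoichiometry
    )
    mu_default = hg.fba(cdm_core).objective_value
    mu_variant = hg.fba(swapped).objective_value
    assert mu_variant != pytest.approx(mu_default, rel=1e-3)
    # swapped model still audits cleanly (pseudo-reactions exempt)
    assert hg.qc_report(swapped, check_loops=False).mass_unbalanced == []


def test_biomass_swap_requires_macromolecule_definitions(cdm_core):
    incomplete = hg.make_biomass_spec("swap_variant_B")
    del incomplete.synthesis["rna"]
    with pytest.raises(ValueError):
        hg.biomass_swap(cdm_core, incomplete)
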