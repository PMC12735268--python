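"""The named computational experiments as replayable pipeline stages.

Each protocol is a pure function over a model: media application, substrate
and oxygen exchange-profile sweeps (FBA + pFBA + FVA per grid point),
NADH/NADPH turnover accounting, the D-gluconate-shunt vs transhydrogenase
comparison, grouped biomass-equation sensitivity analysis, maintenance
(NGAM) sensitivity, and biomass-equation swapping. Protocols never mutate
their input model; infeasible grid points are recorded as data, not raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .biomass import BiomassSpec
from .io import MediumSpec
from .lp import FluxSolution, fba, fva, pfba
from .model import MetabolicModel

__all__ = [
    "SweepResult",
    "SensitivityResult",
    "CofactorTurnover",
    "apply_medium",
    "substrate_sweep",
    "oxygen_sweep",
    "cofactor_turnover",
    "shunt_comparison",
    "biomass_sensitivity",
    "ngam_sensitivity",
    "biomass_swap",
]

log = logging.getLogger("heterogem.protocols")

#: Exchanges tracked by default in sweeps: the heterofermentative products.
DEFAULT_TRACKED = ("EX_lac__L_e", "EX_etoh_e", "EX_ac_e", "EX_co2_e")


def apply_medium(
    model: MetabolicModel, medium: MediumSpec, inplace: bool = False
) -> MetabolicModel:
    """Constrain exchange uptake to the medium's caps.

    Every exchange listed in the medium gets lower bound −cap; every other
    exchange gets lower bound 0 (uptake closed, secretion unchanged).
    Medium entries with no matching exchange are reported via logging, not
    raised.
    """
    if not inplace:
        model = model.copy()
    exchange_ids = {r.id for r in model.exchanges()}
    missing = sorted(set(medium.uptake) - exchange_ids)
    if missing:
        log.warning("medium entries without a model exchange: %s", missing)
    for rxn in model.exchanges():
        cap = medium.uptake.get(rxn.id, 0.0)
        rxn.lower_bound = -cap
        if rxn.id in medium.secretion:
            rxn.upper_bound = medium.secretion[rxn.id]
    return model


@dataclass
class SweepResult:
    """One exchange-profile sweep: growth and product envelopes per point."""

    variable: str
    values: list[float]
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {self.variable: row["value"], "status": row["status"],
                   "growth": row.get("growth")}
            for exch, flux in (row.get("pfba") or {}).items():
                rec[f"{exch}_pfba"] = flux
            for exch, (lo, hi) in (row.get("fva") or {}).items():
                rec[f"{exch}_min"] = lo
                rec[f"{exch}_max"] = hi
            records.append(rec)
        return pd.DataFrame.from_records(records)


def _sweep(model, sweep_exchange, grid, tracked, fraction) -> SweepResult:
    grid = [float(g) for g in grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("sweep grid must be strictly increasing")
    tracked = [t for t in tracked if t in model.reactions]
    result = SweepResult(variable=sweep_exchange, values=grid)
    for g in grid:
        model.reactions[sweep_exchange].lower_bound = -g
        sol = fba(model)
        if not sol.optimal:
            result.rows.append({"value": g, "status": sol.status})
            continue
        point = pfba(model)
        envelope = fva(model, tracked, fraction=fraction)
        result.rows.append(
            {
                "value": g,
                "status": "optimal",
                "growth": sol.objective_value,
                "pfba": {t: point.fluxes[t] for t in tracked},
                "fva": {t: envelope.ranges[t] for t in tracked},
            }
        )
    return result


def substrate_sweep(
    model: MetabolicModel,
    exchange_id: str,
    grid,
    tracked=DEFAULT_TRACKED,
    fraction: float = 1.0,
) -> SweepResult:
    """Vary one substrate's uptake cap over a grid; FBA+pFBA+FVA per point."""
    if exchange_id not in model.reactions:
        raise KeyError(f"exchange {exchange_id!r} not in model")
    return _sweep(model.copy(), exchange_id, grid, tracked, fraction)


def oxygen_sweep(
    model: MetabolicModel,
    glucose_cap: float = 10.0,
    o2_grid=tuple(range(0, 11)),
    tracked=DEFAULT_TRACKED,
    fraction: float = 1.0,
    open_atpase: bool = False,
) -> SweepResult:
    """Sweep oxygen uptake at a fixed glucose uptake rate.

    With ``open_atpase`` the membrane ATPase (reaction id ``ATPase``), when
    the model has one, is opened to (−1000, 1000) so it can run toward ATP
    generation under aerobiosis; models without the reaction proceed with a
    logged notice.
    """
    work = model.copy()
    work.reactions["EX_glc__D_e"].lower_bound = -glucose_cap
    if open_atpase:
        if "ATPase" in work.reactions:
            work.reactions["ATPase"].lower_bound = -1000.0
            work.reactions["ATPase"].upper_bound = 1000.0
        else:
            log.info("no ATPase reaction in model; option ignored")
    return _sweep(work, "EX_o2_e", o2_grid, tracked, fraction)


@dataclass
class CofactorTurnover:
    """Total production-side fluxes of the reduced cofactors.

    "Total NAD(P) flux" is interpreted as the summed production flux of the
    reduced species (NADH resp. NADPH) across all reactions, each reaction
    contributing stoichiometric-coefficient × flux when that product is
    positive under the actual flux direction. The definition is isolated
    here so it can be swapped.
    """

    nadh_production: float
    nadph_production: float

    @property
    def ratio(self) -> float | None:
        if self.nadph_production == 0:
            return None
        return self.nadh_production / self.nadph_production


def cofactor_turnover(
    model: MetabolicModel,
    solution: FluxSolution,
    nadh_id: str = "nadh_c",
    nadph_id: str = "nadph_c",
) -> CofactorTurnover:
    totals = {nadh_id: 0.0, nadph_id: 0.0}
    for rid, flux in solution.fluxes.items():
        stoich = model.reactions[rid].stoichiometry
        for met in totals:
            production = stoich.get(met, 0.0) * flux
            if production > 0:
                totals[met] += production
    return CofactorTurnover(
        nadh_production=totals[nadh_id], nadph_production=totals[nadph_id]
    )


def shunt_comparison(model: MetabolicModel) -> pd.DataFrame:
    """pFBA comparison of redox-balancing variants.

    Four variants of the given model: baseline (shunt and transhydrogenase
    blocked), +NADTRHD, +shunt (GL15LH open), and both. Variants whose
    named reactions are absent are skipped with a notice. The shunt
    fraction is flux(GDH) / glucose uptake.
    """
    has_shunt = "GL15LH" in model.reactions
    has_trhd = "NADTRHD" in model.reactions
    variants = {
        "baseline": (False, False),
        "nadtrhd": (False, True),
        "shunt": (True, False),
        "both": (True, True),
    }
    records = []
    for name, (shunt_on, trhd_on) in variants.items():
        if (shunt_on and not has_shunt) or (trhd_on and not has_trhd):
            log.info("variant %s skipped: required reaction absent", name)
            records.append({"variant": name, "status": "skipped"})
            continue
        work = model.copy()
        if has_shunt:
            work.reactions["GL15LH"].lower_bound = 0.0
            work.reactions["GL15LH"].upper_bound = 1000.0 if shunt_on else 0.0
        if has_trhd:
            trhd = work.reactions["NADTRHD"]
            trhd.lower_bound, trhd.upper_bound = (
                (-1000.0, 1000.0) if trhd_on else (0.0, 0.0)
            )
        sol = pfba(work)
        if not sol.optimal:
            records.append({"variant": name, "status": sol.status})
            continue
        glucose_uptake = -sol.fluxes.get("EX_glc__D_e", 0.0)
        gdh = sol.fluxes.get("GDH", 0.0)
        turnover = cofactor_turnover(work, sol)
        records.append(
            {
                "variant": name,
                "status": "optimal",
                "growth": sol.objective_value,
                "lactate": sol.fluxes.get("EX_lac__L_e"),
                "ethanol": sol.fluxes.get("EX_etoh_e"),
                "co2": sol.fluxes.get("EX_co2_e"),
                "nadh_production": turnover.nadh_production,
                "nadph_production": turnover.nadph_production,
                "shunt_fraction": (gdh / glucose_uptake) if glucose_uptake > 0 else 0.0,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass
class SensitivityResult:
    """Growth response to grouped biomass-coefficient scaling."""

    baseline_growth: float
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.rows)


def biomass_sensitivity(
    model: MetabolicModel,
    biomass_spec: BiomassSpec,
    factors=(0.5, 1.5),
    biomass_id: str = "BIOMASS",
) -> SensitivityResult:
    """Scale each biomass group's coefficients jointly and re-run FBA.

    The ATP-hydrolysis quartet (ATP, H₂O, ADP, Pᵢ, H⁺) scales as one unit
    so its internal mass balance is preserved, and the wall components
    (peptidoglycan + teichoic acid) likewise. Percent change is
    100 × (μ − μ₀)/μ₀. The input model is never modified; factor 1.0 rows
    equal the baseline exactly. Groups absent from the model's biomass
    reaction are skipped with a notice.
    """
    base = fba(model)
    if not base.optimal:
        raise RuntimeError(f"baseline FBA is {base.status}")
    mu0 = base.objective_value
    result = SensitivityResult(baseline_growth=mu0)
    biomass_rxn = model.reactions[biomass_id]
    for group, components in biomass_spec.groups().items():
        member_ids = [c.metabolite for c in components]
        if not all(m in biomass_rxn.stoichiometry for m in member_ids):
            log.info("group %s absent from %s; skipped", group, biomass_id)
            continue
        for factor in factors:
            if factor == 1.0:
                result.rows.append(
                    {"group": group, "factor": 1.0, "status": "optimal",
                     "growth": mu0, "percent_change": 0.0}
                )
                continue
            work = model.copy()
            rxn = work.reactions[biomass_id]
            for met in member_ids:
                rxn.stoichiometry[met] *= factor
            sol = fba(work)
            row = {"group": group, "factor": factor, "status": sol.status}
            if sol.optimal:
                row["growth"] = sol.objective_value
                row["percent_change"] = 100.0 * (sol.objective_value - mu0) / mu0
            result.rows.append(row)
    return result


def ngam_sensitivity(
    model: MetabolicModel, levels=(0.0, 0.36, 0.51), atpm_id: str = "ATPM"
) -> pd.DataFrame:
    """Growth per ATP-maintenance lower bound; percent change vs level 0."""
    if atpm_id not in model.reactions:
        raise KeyError(f"no {atpm_id} reaction in model")
    records = []
    base_growth = None
    for level in levels:
        work = model.copy()
        work.reactions[atpm_id].lower_bound = float(level)
        sol = fba(work)
        rec = {"ngam_lb": float(level), "status": sol.status}
        if sol.optimal:
            rec["growth"] = sol.objective_value
            if base_growth is None:
                base_growth = sol.objective_value
            rec["percent_change"] = (
                100.0 * (sol.objective_value - base_growth) / base_growth
                if base_growth else 0.0
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


_SWAP_METS = ("atp_c", "adp_c", "h2o_c", "h_c", "pi_c",
              "dna_c", "rna_c", "protein_c")


def biomass_swap(
    model: MetabolicModel, alt_spec: BiomassSpec, biomass_id: str = "BIOMASS"
) -> MetabolicModel:
    """Adopt another biomass equation's energy/macromolecule terms.

    Replaces the biomass coefficients for ATP/ADP/H₂O/H⁺/Pᵢ and
    DNA/RNA/protein and the three macromolecule synthesis reactions with
    those of ``alt_spec``; wall-polymer coefficients are left unchanged.
    Returns a new model. Missing macromolecule definitions are an error.
    """
    for macro in ("protein", "dna", "rna"):
        if macro not in alt_spec.synthesis:
            raise ValueError(f"alt spec lacks a {macro} synthesis definition")
    alt_spec.validate()
    work = model.copy()
    rxn = work.reactions[biomass_id]
    alt = alt_spec.stoichiometry()
    for met in _SWAP_METS:
        if met in alt:
            rxn.stoichiometry[met] = alt[met]
        else:
            rxn.stoichiometry.pop(met, None)
    rxn.name = f"biomass equation ({alt_spec.name})"
    for macro in ("protein", "dna", "rna"):
        srxn = work.reactions[macro.upper() + "S"]
        srxn.stoichiometry = dict(alt_spec.synthesis[macro])
    return work
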