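import numpy as np
import pytest

import heterogem as hg
from heterogem.model import MetabolicModel, Metabolite, Reaction, parse_formula


@pytest.fixture(scope="session")
def core_model():
    return hg.build_core_model()


@pytest.fixture(scope="session")
def core_on_cdm(core_model):
    return hg.apply_medium(core_model, hg.cdm_medium())


@pytest.fixture(scope="session")
def core_qc(core_model):
    return hg.qc_report(core_model)


def simple_chain_model():
    """EX_A (uptake 10) -> A -> B -> EX_B, objective EX_B."""
    m = MetabolicModel("chain")
    for mid, comp in [("a_e", "e"), ("a_c", "c"), ("b_c", "c"), ("b_e", "e")]:
        m.add_metabolite(Metabolite(mid, mid, comp, parse_formula("CH2O"), 0))
    m.add_reaction(Reaction("EX_a_e", "", {"a_e": -1}, -10, 1000, kind="exchange"))
    m.add_reaction(Reaction("At", "", {"a_e": -1, "a_c": 1}, 0, 1000))
    m.add_reaction(Reaction("AB", "", {"a_c": -1, "b_c": 1}, 0, 1000))
    m.add_reaction(Reaction("Bt", "", {"b_c": -1, "b_e": 1}, 0, 1000))
    m.add_reaction(Reaction("EX_b_e", "", {"b_e": -1}, 0, 1000, kind="exchange"))
    m.set_objective("EX_b_e")
    return m


def random_network(rng: np.random.Generator) -> MetabolicModel:
    """A small random stoichiometric network with boundary exchanges.

    Used for oracle-equivalence testing; not guaranteed feasible or
    interesting, which is the point — statuses must agree too.
    """
    n_mets = int(rng.integers(3, 8))
    n_internal = int(rng.integers(3, 12))
    m = MetabolicModel("random")
    for i in range(n_mets):
        m.add_metabolite(Metabolite(f"m{i}_c", f"m{i}", "c"))
    n_exch = int(rng.integers(2, min(4, n_mets) + 1))
    exch_mets = rng.choice(n_mets, size=n_exch, replace=False)
    for k, i in enumerate(exch_mets):
        mid = f"x{i}_e"
        m.add_metabolite(Metabolite(mid, mid, "e"))
        m.add_reaction(
            Reaction(f"T{i}", "", {f"m{i}_c": -1, mid: 1}, -1000, 1000)
        )
        lb = -float(rng.integers(0, 11)) if k < 2 else 0.0
        m.add_reaction(
            Reaction(f"EX_{mid}", "", {mid: -1}, lb, 1000, kind="exchange")
        )
    for j in range(n_internal):
        size = int(rng.integers(2, 4))
        mets = rng.choice(n_mets, size=size, replace=False)
        stoich = {}
        for idx, i in enumerate(mets):
            coeff = float(rng.choice([-2, -1, 1, 2]))
            if idx == 0:
                coeff = -abs(coeff)
            elif idx == size - 1:
                coeff = abs(coeff)
            stoich[f"m{i}_c"] = coeff
        lb, ub = (-1000.0, 1000.0) if rng.random() < 0.5 else (0.0, 1000.0)
        m.add_reaction(Reaction(f"R{j}", "", stoich, lb, ub))
    m.set_objective(f"EX_x{exch_mets[-1]}_e")
    return m


def to_cobra(model: MetabolicModel):
    """Independent conversion to a cobrapy model (test oracle only)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        mid: cobra.Metabolite(mid, compartment=met.compartment)
        for mid, met in model.metabolites.items()
    }
    for rid, rxn in model.reactions.items():
        cr = cobra.Reaction(rid, lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[mid]: c for mid, c in rxn.stoichiometry.items()})
    cm.objective = model.objective_id
    return cm
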