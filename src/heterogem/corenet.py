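"""Deterministic generator for a heterofermentative LAB core network.

The generated model embodies the metabolism of an obligately
heterofermentative lactic acid bacterium: sugars enter the phosphoketolase
(pentose phosphate) route — there is deliberately no phosphofructokinase or
aldolase — and are fermented to lactate plus ethanol/acetate and CO₂.
Glucose 6-phosphate can be oxidized two ways:

* the classical oxidative PPP (hexokinase → G6P dehydrogenase →
  6-phosphogluconolactonase → 6PG dehydrogenase), yielding 2 NADPH + 1 NADH
  per glucose together with lower glycolysis; or
* the D-gluconate shunt (NAD-dependent glucose 1-dehydrogenase →
  gluconolactonase GL15LH → gluconate kinase), in which the first oxidation
  regenerates NADH instead of NADPH, yielding 2 NADH + 1 NADPH per glucose.

Anaerobic fermentation to lactate + ethanol demands exactly 2 NADH + 1
NADPH per glucose under the default ``mixed_NADH_NADPH`` ethanol-branch
policy (acetaldehyde reduction NADPH-linked, acetyl-CoA reduction
NADH-linked), so the shunt closes the redox balance exactly while the
classical route cannot — the stoichiometric mechanism behind the
1:1:1 lactate:ethanol:CO₂ fermentation profile. Under ``strict_NADH`` the
ethanol branch consumes NADH only and the NADPH forced out of the 6PG
dehydrogenase can only be reinvested in biosynthesis, which throttles (or
abolishes) growth unless the shunt or a transhydrogenase is available.

Every internal reaction is mass- and charge-balanced (verified by the QC
audits in the test suite); biomass, macromolecule synthesis, and
maintenance pseudo-reactions are exempt by kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biomass import BiomassSpec, make_biomass_spec
from .ledger import Edit, EditLedger
from .model import MetabolicModel, Metabolite, Reaction, parse_formula

__all__ = [
    "CoreConfig",
    "build_core_model",
    "declared_inventory",
    "make_loop_fixture",
    "make_broken_fixture",
    "repair_ledger",
    "make_biomass_spec",
]

BIG = 1000.0


@dataclass
class CoreConfig:
    """Switches and policies for the core-network generator.

    ``ngam_lb`` is the non-growth-associated maintenance floor on the ATPM
    reaction in mmol·gDCW⁻¹·h⁻¹; 0.51 is the default adopted from
    experimentally validated LAB maintenance values (0 and 0.36 are the
    other conventional settings). ``bound_jitter`` optionally perturbs the
    ±1000 default bounds multiplicatively for robustness tests, driven by
    ``seed`` (the generator is otherwise fully deterministic).
    """

    include_shunt: bool = True
    include_classical_ppp: bool = True
    include_nadtrhd: bool = False
    include_nox: bool = True
    include_adi: bool = True
    include_leloir: bool = True
    include_lactose: bool = True
    include_malolactic: bool = True
    include_butanediol: bool = True
    g6pdh_cofactor: str = "NADP"  # NADP | NAD
    ethanol_branch: str = "mixed_NADH_NADPH"  # strict_NADH | mixed_NADH_NADPH
    biomass: BiomassSpec = field(default_factory=make_biomass_spec)
    ngam_lb: float = 0.51
    seed: int = 42
    bound_jitter: float = 0.0

    def validate(self) -> None:
        if not (self.include_shunt or self.include_classical_ppp):
            raise ValueError("at least one glucose-activation route must be enabled")
        if self.include_lactose and not self.include_leloir:
            raise ValueError("lactose utilization requires the Leloir pathway")
        if self.g6pdh_cofactor not in ("NADP", "NAD"):
            raise ValueError(f"bad g6pdh_cofactor {self.g6pdh_cofactor!r}")
        if self.ethanol_branch not in ("strict_NADH", "mixed_NADH_NADPH"):
            raise ValueError(f"bad ethanol_branch {self.ethanol_branch!r}")


# id, name, compartment, formula, charge
_METS = [
    ("glc__D_e", "D-glucose", "e", "C6H12O6", 0),
    ("glc__D_c", "D-glucose", "c", "C6H12O6", 0),
    ("g6p_c", "D-glucose 6-phosphate", "c", "C6H11O9P", -2),
    ("g15lac_c", "D-glucono-1,5-lactone", "c", "C6H10O6", 0),
    ("glcn_c", "D-gluconate", "c", "C6H11O7", -1),
    ("6pgl_c", "6-phospho-D-glucono-1,5-lactone", "c", "C6H9O9P", -2),
    ("6pgc_c", "6-phospho-D-gluconate", "c", "C6H10O10P", -3),
    ("ru5p__D_c", "D-ribulose 5-phosphate", "c", "C5H9O8P", -2),
    ("xu5p__D_c", "D-xylulose 5-phosphate", "c", "C5H9O8P", -2),
    ("g3p_c", "glyceraldehyde 3-phosphate", "c", "C3H5O6P", -2),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H2O6P", -3),
    ("pyr_c", "pyruvate", "c", "C3H3O3", -1),
    ("lac__L_c", "L-lactate", "c", "C3H5O3", -1),
    ("lac__L_e", "L-lactate", "e", "C3H5O3", -1),
    ("actp_c", "acetyl phosphate", "c", "C2H3O5P", -2),
    ("ac_c", "acetate", "c", "C2H3O2", -1),
    ("ac_e", "acetate", "e", "C2H3O2", -1),
    ("accoa_c", "acetyl-CoA", "c", "C23H34N7O17P3S", -4),
    ("coa_c", "coenzyme A", "c", "C21H32N7O16P3S", -4),
    ("acald_c", "acetaldehyde", "c", "C2H4O", 0),
    ("etoh_c", "ethanol", "c", "C2H6O", 0),
    ("etoh_e", "ethanol", "e", "C2H6O", 0),
    ("co2_c", "carbon dioxide", "c", "CO2", 0),
    ("co2_e", "carbon dioxide", "e", "CO2", 0),
    ("o2_c", "oxygen", "c", "O2", 0),
    ("o2_e", "oxygen", "e", "O2", 0),
    ("h2o_c", "water", "c", "H2O", 0),
    ("h2o_e", "water", "e", "H2O", 0),
    ("h_c", "proton", "c", "H", 1),
    ("h_e", "proton", "e", "H", 1),
    ("pi_c", "phosphate", "c", "HO4P", -2),
    ("pi_e", "phosphate", "e", "HO4P", -2),
    ("nh4_c", "ammonium", "c", "H4N", 1),
    ("nh4_e", "ammonium", "e", "H4N", 1),
    ("atp_c", "ATP", "c", "C10H12N5O13P3", -4),
    ("adp_c", "ADP", "c", "C10H12N5O10P2", -3),
    ("nad_c", "NAD+", "c", "C21H26N7O14P2", -1),
    ("nadh_c", "NADH", "c", "C21H27N7O14P2", -2),
    ("nadp_c", "NADP+", "c", "C21H25N7O17P3", -3),
    ("nadph_c", "NADPH", "c", "C21H26N7O17P3", -4),
    ("protein_c", "protein (biomass macromolecule)", "c", "X", 0),
    ("dna_c", "DNA (biomass macromolecule)", "c", "X", 0),
    ("rna_c", "RNA (biomass macromolecule)", "c", "X", 0),
    ("ptg_c", "peptidoglycan (wall polymer)", "c", "X", 0),
    ("tca_c", "teichoic acid (wall polymer)", "c", "X", 0),
]

_MET_ADI = [
    ("arg__L_e", "L-arginine", "e", "C6H15N4O2", 1),
    ("arg__L_c", "L-arginine", "c", "C6H15N4O2", 1),
    ("citr__L_c", "L-citrulline", "c", "C6H13N3O3", 0),
    ("orn_c", "ornithine", "c", "C5H13N2O2", 1),
    ("orn_e", "ornithine", "e", "C5H13N2O2", 1),
    ("cbp_c", "carbamoyl phosphate", "c", "CH2NO5P", -2),
]

_MET_LELOIR = [
    ("gal_e", "D-galactose", "e", "C6H12O6", 0),
    ("gal_c", "D-galactose", "c", "C6H12O6", 0),
    ("gal1p_c", "galactose 1-phosphate", "c", "C6H11O9P", -2),
    ("g1p_c", "glucose 1-phosphate", "c", "C6H11O9P", -2),
    ("udpg_c", "UDP-glucose", "c", "C15H22N2O17P2", -2),
    ("udpgal_c", "UDP-galactose", "c", "C15H22N2O17P2", -2),
]

_MET_LACTOSE = [("lcts_e", "lactose", "e", "C12H22O11", 0)]
_MET_MALOLACTIC = [
    ("mal__L_e", "L-malate", "e", "C4H4O5", -2),
    ("mal__L_c", "L-malate", "c", "C4H4O5", -2),
]
_MET_BUTANEDIOL = [
    ("alac__S_c", "(S)-2-acetolactate", "c", "C5H7O4", -1),
    ("actn_c", "S-acetoin", "c", "C4H8O2", 0),
    ("btd_RR_c", "2,3-butanediol", "c", "C4H10O2", 0),
    ("btd_RR_e", "2,3-butanediol", "e", "C4H10O2", 0),
]


def _rxn(rid, name, stoich, lb, ub, gpr=None, subsystem="", kind="internal"):
    return Reaction(
        id=rid, name=name, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        gpr=gpr, subsystem=subsystem, kind=kind,
    )


def _reaction_table(config: CoreConfig) -> tuple[list, list[Reaction]]:
    """The declared inventory: metabolite rows and Reaction objects."""
    config.validate()
    mets = list(_METS)
    rxns: list[Reaction] = []
    exchange_mets = [
        "glc__D_e", "lac__L_e", "etoh_e", "ac_e", "co2_e", "o2_e",
        "h2o_e", "h_e", "pi_e", "nh4_e",
    ]

    # -- glucose uptake and activation --------------------------------------
    rxns += [
        _rxn("GLCpts", "glucose PEP phosphotransferase uptake",
             {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1},
             0, BIG, gpr="LKD_0101 and LKD_0102", subsystem="transport"),
        _rxn("GLCt2", "glucose proton symport",
             {"glc__D_e": -1, "h_e": -1, "glc__D_c": 1, "h_c": 1},
             0, BIG, gpr="LKD_0103", subsystem="transport"),
    ]
    if config.include_classical_ppp:
        nad_pair = ("nadp_c", "nadph_c") if config.g6pdh_cofactor == "NADP" else (
            "nad_c", "nadh_c")
        rxns += [
            _rxn("HEX1", "hexokinase",
                 {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0104", subsystem="upper catabolism"),
            _rxn("G6PDH2r", f"glucose-6-phosphate dehydrogenase ({config.g6pdh_cofactor})",
                 {"g6p_c": -1, nad_pair[0]: -1, "6pgl_c": 1, nad_pair[1]: 1, "h_c": 1},
                 0, BIG, gpr="LKD_0105", subsystem="oxidative PPP"),
            _rxn("PGL", "6-phosphogluconolactonase",
                 {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0106", subsystem="oxidative PPP"),
        ]
    if config.include_shunt:
        rxns += [
            _rxn("GDH", "glucose 1-dehydrogenase (NAD)",
                 {"glc__D_c": -1, "nad_c": -1, "g15lac_c": 1, "nadh_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0110", subsystem="D-gluconate shunt"),
            _rxn("GL15LH", "gluconolactonase",
                 {"g15lac_c": -1, "h2o_c": -1, "glcn_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0111", subsystem="D-gluconate shunt"),
            _rxn("GNK", "gluconate kinase",
                 {"glcn_c": -1, "atp_c": -1, "6pgc_c": 1, "adp_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0112", subsystem="D-gluconate shunt"),
        ]
    rxns += [
        _rxn("GND", "6-phosphogluconate dehydrogenase (NADP)",
             {"6pgc_c": -1, "nadp_c": -1, "ru5p__D_c": 1, "co2_c": 1, "nadph_c": 1},
             0, BIG, gpr="LKD_0107", subsystem="oxidative PPP"),
        _rxn("RPE", "ribulose-5-phosphate 3-epimerase",
             {"ru5p__D_c": -1, "xu5p__D_c": 1},
             -BIG, BIG, gpr="LKD_0108", subsystem="PPP"),
        _rxn("PKETX", "phosphoketolase (xylulose 5-phosphate)",
             {"xu5p__D_c": -1, "pi_c": -1, "g3p_c": 1, "actp_c": 1, "h2o_c": 1},
             0, BIG, gpr="LKD_0109 or LKD_0113", subsystem="phosphoketolase"),
        # lumped GAPD+PGK+PGM+ENO: net ATP/NADH stoichiometry preserved
        _rxn("GLYCLOW", "lower glycolysis (lumped GAPD/PGK/PGM/ENO)",
             {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "adp_c": -1,
              "pep_c": 1, "nadh_c": 1, "atp_c": 1, "h2o_c": 1, "h_c": 1},
             0, BIG, gpr="LKD_0120 and LKD_0121", subsystem="lower glycolysis"),
        _rxn("PYK", "pyruvate kinase",
             {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
             0, BIG, gpr="LKD_0122", subsystem="lower glycolysis"),
        _rxn("LDH_L", "L-lactate dehydrogenase",
             {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__L_c": 1, "nad_c": 1},
             0, BIG, gpr="LKD_0130", subsystem="fermentation"),
        _rxn("PTAr", "phosphotransacetylase",
             {"actp_c": -1, "coa_c": -1, "accoa_c": 1, "pi_c": 1},
             -BIG, BIG, gpr="LKD_0131", subsystem="fermentation"),
        _rxn("ACKr", "acetate kinase",
             {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
             -BIG, BIG, gpr="LKD_0132", subsystem="fermentation"),
        _rxn("ACALD", "acetaldehyde dehydrogenase (acetylating, NADH)",
             {"accoa_c": -1, "nadh_c": -1, "h_c": -1,
              "acald_c": 1, "coa_c": 1, "nad_c": 1},
             0, BIG, gpr="LKD_0133", subsystem="fermentation"),
    ]
    if config.ethanol_branch == "mixed_NADH_NADPH":
        rxns.append(
            _rxn("ALCD2y", "alcohol dehydrogenase (NADPH)",
                 {"acald_c": -1, "nadph_c": -1, "h_c": -1, "etoh_c": 1, "nadp_c": 1},
                 0, BIG, gpr="LKD_0134", subsystem="fermentation"))
    else:
        rxns.append(
            _rxn("ALCD2x", "alcohol dehydrogenase (NADH)",
                 {"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
                 0, BIG, gpr="LKD_0134", subsystem="fermentation"))

    if config.include_nox:
        rxns += [
            _rxn("NOX", "NADH oxidase (water-forming)",
                 {"nadh_c": -1, "o2_c": -0.5, "h_c": -1, "nad_c": 1, "h2o_c": 1},
                 0, BIG, gpr="LKD_0140", subsystem="oxygen metabolism"),
            # the NADPH-accepting activity of the same promiscuous oxidase
            _rxn("NOXP", "NAD(P)H oxidase, NADPH-accepting activity",
                 {"nadph_c": -1, "o2_c": -0.5, "h_c": -1, "nadp_c": 1, "h2o_c": 1},
                 0, BIG, gpr="LKD_0140", subsystem="oxygen metabolism"),
        ]
    if config.include_nadtrhd:
        rxns.append(
            _rxn("NADTRHD", "NAD transhydrogenase (diagnostic pseudo-reaction)",
                 {"nad_c": -1, "nadph_c": -1, "nadh_c": 1, "nadp_c": 1},
                 -BIG, BIG, subsystem="redox"))

    rxns.append(
        _rxn("ATPM", "ATP maintenance (NGAM)",
             {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
             config.ngam_lb, BIG, kind="maintenance", subsystem="maintenance"))

    if config.include_adi:
        mets += _MET_ADI
        exchange_mets += ["arg__L_e", "orn_e"]
        rxns += [
            _rxn("ARGORNt", "arginine/ornithine antiport",
                 {"arg__L_e": -1, "orn_c": -1, "arg__L_c": 1, "orn_e": 1},
                 0, BIG, gpr="LKD_0150", subsystem="ADI pathway"),
            _rxn("ARGDI", "arginine deiminase",
                 {"arg__L_c": -1, "h2o_c": -1, "citr__L_c": 1, "nh4_c": 1},
                 0, BIG, gpr="LKD_0151", subsystem="ADI pathway"),
            _rxn("OCBT", "ornithine transcarbamylase (catabolic direction)",
                 {"citr__L_c": -1, "pi_c": -1, "h_c": -1, "cbp_c": 1, "orn_c": 1},
                 0, BIG, gpr="LKD_0152", subsystem="ADI pathway"),
            _rxn("CBMK", "carbamate kinase (ATP-forming)",
                 {"cbp_c": -1, "adp_c": -1, "h_c": -2,
                  "atp_c": 1, "co2_c": 1, "nh4_c": 1},
                 0, BIG, gpr="LKD_0153", subsystem="ADI pathway"),
        ]
    if config.include_leloir:
        mets += _MET_LELOIR
        exchange_mets += ["gal_e"]
        rxns += [
            _rxn("GALt2", "galactose proton symport",
                 {"gal_e": -1, "h_e": -1, "gal_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0160", subsystem="transport"),
            _rxn("GALK", "galactokinase",
                 {"gal_c": -1, "atp_c": -1, "gal1p_c": 1, "adp_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0161", subsystem="Leloir pathway"),
            _rxn("UGLT", "galactose-1-phosphate uridylyltransferase",
                 {"gal1p_c": -1, "udpg_c": -1, "g1p_c": 1, "udpgal_c": 1},
                 -BIG, BIG, gpr="LKD_0162", subsystem="Leloir pathway"),
            _rxn("UDPG4E", "UDP-glucose 4-epimerase",
                 {"udpgal_c": -1, "udpg_c": 1},
                 -BIG, BIG, gpr="LKD_0163", subsystem="Leloir pathway"),
            _rxn("PGMT", "phosphoglucomutase",
                 {"g1p_c": -1, "g6p_c": 1},
                 -BIG, BIG, gpr="LKD_0164", subsystem="Leloir pathway"),
        ]
    if config.include_lactose:
        mets += _MET_LACTOSE
        exchange_mets += ["lcts_e"]
        rxns.append(
            _rxn("LCTSH", "extracellular lactose hydrolysis",
                 {"lcts_e": -1, "h2o_e": -1, "glc__D_e": 1, "gal_e": 1},
                 0, BIG, gpr="LKD_0165", subsystem="lactose utilization"))
    if config.include_malolactic:
        mets += _MET_MALOLACTIC
        exchange_mets += ["mal__L_e"]
        rxns += [
            _rxn("MALt2", "malate proton symport",
                 {"mal__L_e": -1, "h_e": -1, "mal__L_c": 1, "h_c": 1},
                 0, BIG, gpr="LKD_0170", subsystem="transport"),
            _rxn("MALLAC", "malolactic enzyme",
                 {"mal__L_c": -1, "h_c": -1, "lac__L_c": 1, "co2_c": 1},
                 0, BIG, gpr="LKD_0171", subsystem="malolactic fermentation"),
        ]
    if config.include_butanediol:
        mets += _MET_BUTANEDIOL
        exchange_mets += ["btd_RR_e"]
        rxns += [
            _rxn("ACLS", "acetolactate synthase",
                 {"pyr_c": -2, "h_c": -1, "alac__S_c": 1, "co2_c": 1},
                 0, BIG, gpr="LKD_0180", subsystem="butanediol pathway"),
            _rxn("ACLDC", "acetolactate decarboxylase",
                 {"alac__S_c": -1, "h_c": -1, "actn_c": 1, "co2_c": 1},
                 0, BIG, gpr="LKD_0181", subsystem="butanediol pathway"),
            _rxn("BTDD", "butanediol dehydrogenase",
                 {"actn_c": -1, "nadh_c": -1, "h_c": -1, "btd_RR_c": 1, "nad_c": 1},
                 0, BIG, gpr="LKD_0182", subsystem="butanediol pathway"),
            _rxn("BTDt", "butanediol export",
                 {"btd_RR_c": -1, "btd_RR_e": 1},
                 0, BIG, subsystem="transport"),
        ]

    # -- small-molecule transport -------------------------------------------
    rxns += [
        _rxn("L_LACt2r", "lactate proton symport",
             {"lac__L_e": -1, "h_e": -1, "lac__L_c": 1, "h_c": 1},
             -BIG, BIG, gpr="LKD_0190", subsystem="transport"),
        _rxn("ETOHt", "ethanol diffusion",
             {"etoh_e": -1, "etoh_c": 1}, -BIG, BIG, subsystem="transport"),
        _rxn("ACt2r", "acetate proton symport",
             {"ac_e": -1, "h_e": -1, "ac_c": 1, "h_c": 1},
             -BIG, BIG, gpr="LKD_0191", subsystem="transport"),
        _rxn("CO2t", "CO2 diffusion", {"co2_e": -1, "co2_c": 1}, -BIG, BIG,
             subsystem="transport"),
        _rxn("O2t", "O2 diffusion", {"o2_e": -1, "o2_c": 1}, -BIG, BIG,
             subsystem="transport"),
        _rxn("H2Ot", "water diffusion", {"h2o_e": -1, "h2o_c": 1}, -BIG, BIG,
             subsystem="transport"),
        _rxn("Ht", "proton leak", {"h_e": -1, "h_c": 1}, -BIG, BIG,
             subsystem="transport"),
        _rxn("NH4t", "ammonium transport", {"nh4_e": -1, "nh4_c": 1}, -BIG, BIG,
             subsystem="transport"),
        _rxn("PIt", "phosphate transport", {"pi_e": -1, "pi_c": 1}, -BIG, BIG,
             gpr="LKD_0192", subsystem="transport"),
    ]

    # -- biomass and macromolecule synthesis --------------------------------
    bm = config.biomass
    bm.validate()
    for macro in ("protein", "dna", "rna"):
        rxns.append(
            _rxn(macro.upper() + "S", f"{macro} synthesis (lumped pseudo-reaction)",
                 dict(bm.synthesis[macro]), 0, BIG, kind="biomass",
                 subsystem="biomass"))
    rxns += [
        _rxn("PTGS", "peptidoglycan synthesis (lumped pseudo-reaction)",
             {"g6p_c": -2, "pyr_c": -1, "nh4_c": -1, "ptg_c": 1},
             0, BIG, kind="biomass", subsystem="biomass"),
        _rxn("TCAS", "teichoic acid synthesis (lumped pseudo-reaction)",
             {"g6p_c": -1.5, "tca_c": 1},
             0, BIG, kind="biomass", subsystem="biomass"),
        _rxn("BIOMASS", f"biomass equation ({bm.name})",
             bm.stoichiometry(), 0, BIG, kind="biomass", subsystem="biomass"),
    ]

    # -- exchanges ------------------------------------------------------------
    for met_id in exchange_mets:
        rxns.append(
            _rxn("EX_" + met_id, f"exchange for {met_id}",
                 {met_id: -1.0}, -BIG, BIG, kind="exchange", subsystem="exchange"))
    return mets, rxns


def build_core_model(config: CoreConfig | None = None) -> MetabolicModel:
    """Generate the core model; deterministic for a given config and seed."""
    config = config or CoreConfig()
    mets, rxns = _reaction_table(config)
    model = MetabolicModel("lab_core")
    for mid, name, comp, formula, charge in mets:
        model.add_metabolite(
            Metabolite(id=mid, name=name, compartment=comp,
                       formula=parse_formula(formula), charge=charge))
    if config.bound_jitter > 0:
        rng = np.random.default_rng(config.seed)
        for rxn in rxns:
            scale = 1.0 + config.bound_jitter * rng.uniform(-1, 1)
            if rxn.lower_bound == -BIG:
                rxn.lower_bound = -BIG * scale
            if rxn.upper_bound == BIG:
                rxn.upper_bound = BIG * scale
    for rxn in rxns:
        model.add_reaction(rxn)
    model.set_objective("BIOMASS")
    model.validate()
    return model


def declared_inventory(config: CoreConfig | None = None) -> dict[str, int]:
    """Counts implied by the generator's reaction table (for audits)."""
    config = config or CoreConfig()
    mets, rxns = _reaction_table(config)
    genes = set()
    for r in rxns:
        genes |= r.genes
    return {
        "genes": len(genes),
        "reactions": len(rxns),
        "reactions_without_gpr": sum(1 for r in rxns if r.gpr is None),
        "metabolites": len(mets),
    }


# ---------------------------------------------------------------------------
# QC fixtures


def make_loop_fixture() -> MetabolicModel:
    """A reversible 3-cycle plus a disjoint boundary-connected linear path.

    Exactly the three cycle reactions can carry flux with all boundaries
    closed; the linear pathway cannot.
    """
    model = MetabolicModel("loop_fixture")
    for mid, name in [
        ("cyc_a_c", "cycle carrier A"), ("cyc_b_c", "cycle carrier B"),
        ("cyc_c_c", "cycle carrier C"),
        ("lin_x_e", "linear substrate"), ("lin_x_c", "linear substrate"),
        ("lin_y_c", "linear product"), ("lin_y_e", "linear product"),
    ]:
        comp = "e" if mid.endswith("_e") else "c"
        model.add_metabolite(
            Metabolite(id=mid, name=name, compartment=comp,
                       formula=parse_formula("CH2O"), charge=0))
    for rid, stoich in [
        ("CYCAB", {"cyc_a_c": -1, "cyc_b_c": 1}),
        ("CYCBC", {"cyc_b_c": -1, "cyc_c_c": 1}),
        ("CYCCA", {"cyc_c_c": -1, "cyc_a_c": 1}),
    ]:
        model.add_reaction(_rxn(rid, rid, stoich, -BIG, BIG))
    model.add_reaction(_rxn("LINt", "substrate uptake",
                            {"lin_x_e": -1, "lin_x_c": 1}, 0, BIG))
    model.add_reaction(_rxn("LIN1", "linear conversion",
                            {"lin_x_c": -1, "lin_y_c": 1}, 0, BIG))
    model.add_reaction(_rxn("LINt2", "product export",
                            {"lin_y_c": -1, "lin_y_e": 1}, 0, BIG))
    for met in ("lin_x_e", "lin_y_e"):
        model.add_reaction(
            _rxn("EX_" + met, f"exchange for {met}", {met: -1.0}, -BIG, BIG,
                 kind="exchange"))
    return model


def make_broken_fixture(config: CoreConfig | None = None) -> MetabolicModel:
    """The core model with injected draft-reconstruction pathologies.

    Exactly: 3 mass-unbalanced reactions, 1 charge-unbalanced reaction,
    1 duplicate-metabolite pair carrying 1 would-be-duplicate reaction,
    1 literal duplicate reaction, 1 dead-end metabolite, and a reversible
    3-cycle (3 loop-capable reactions). ``repair_ledger()`` fixes all of
    them.
    """
    model = build_core_model(config)
    model.id = "lab_core_broken"
    # mass-unbalanced (charge fine): carbon/oxygen or hydrogen slips
    model.add_reaction(_rxn("BRK1", "broken decarboxylation (loses a carbon)",
                            {"pyr_c": -1, "ac_c": 1}, 0, BIG))
    model.add_reaction(_rxn("BRK2", "broken lactonase (drops water)",
                            {"6pgl_c": -1, "6pgc_c": 1, "h_c": 1}, 0, BIG))
    model.add_reaction(_rxn("BRK3", "broken oxidation (no cofactor)",
                            {"etoh_c": -1, "acald_c": 1}, 0, BIG))
    # charge-unbalanced, mass fine: stereo twin with a wrong charge
    model.add_metabolite(Metabolite("lac__D_c", "D-lactate", "c",
                                    parse_formula("C3H5O3"), 0))
    model.add_reaction(_rxn("BRK4", "lactate racemase (mis-charged product)",
                            {"lac__L_c": -1, "lac__D_c": 1}, -BIG, BIG))
    # duplicate metabolite with its shadow reaction
    model.add_metabolite(Metabolite("actn2_c", "(S)-acetoin", "c",
                                    parse_formula("C4H8O2"), 0))
    model.add_reaction(_rxn("BTDD2", "butanediol dehydrogenase (duplicate entry)",
                            {"actn2_c": -1, "nadh_c": -1, "h_c": -1,
                             "btd_RR_c": 1, "nad_c": 1},
                            -BIG, BIG, gpr="LKD_0182"))
    # literal duplicate reaction
    model.add_reaction(_rxn("LDH2", "L-lactate dehydrogenase (duplicate entry)",
                            {"pyr_c": -1, "nadh_c": -1, "h_c": -1,
                             "lac__L_c": 1, "nad_c": 1}, 0, BIG))
    # dead end
    model.add_metabolite(Metabolite("junk_c", "uncharacterized intermediate",
                                    "c", parse_formula("C3H3O3"), -1))
    model.add_reaction(_rxn("DEADX", "orphan side-product formation",
                            {"pyr_c": -1, "junk_c": 1}, 0, BIG))
    # reversible triangle (thermodynamically infeasible loop)
    for tag in "abc":
        model.add_metabolite(Metabolite(f"tri_{tag}_c", f"loop metabolite {tag}",
                                        "c", parse_formula("C2H4O2"), 0))
    model.add_reaction(_rxn("TRIA", "loop edge a-b",
                            {"tri_a_c": -1, "tri_b_c": 1}, -BIG, BIG))
    model.add_reaction(_rxn("TRIB", "loop edge b-c",
                            {"tri_b_c": -1, "tri_c_c": 1}, -BIG, BIG))
    model.add_reaction(_rxn("TRIC", "loop edge c-a",
                            {"tri_c_c": -1, "tri_a_c": 1}, -BIG, BIG))
    return model


def repair_ledger() -> EditLedger:
    """The shipped curation ledger fixing every defect in the broken fixture."""
    ledger = EditLedger()
    for rid in ("BRK1", "BRK2", "BRK3"):
        ledger.append(Edit("remove_reaction", rid,
                           rationale="mass-unbalanced; no genomic support"))
    ledger.append(Edit("remove_reaction", "BRK4",
                       rationale="charge-unbalanced racemase entry"))
    ledger.append(Edit("merge_metabolites", "actn_c", {"drop_id": "actn2_c"},
                       rationale="duplicate acetoin entry; duplicate reaction collapses"))
    ledger.append(Edit("remove_reaction", "LDH2",
                       rationale="literal duplicate of LDH_L"))
    ledger.append(Edit("add_demand", "junk_c",
                       rationale="dead-end resolved by a demand reaction"))
    ledger.append(Edit("block_reaction", "TRIC",
                       rationale="breaks the thermodynamically infeasible cycle"))
    return ledger
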