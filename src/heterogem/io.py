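"""Model and configuration I/O.

SBML is read and written as Level 3 Version 1 with the flux-balance-
constraints (fbc v2) extension — bounds as shared parameter objects,
gene products with association trees, and an active maximization
objective — which is what current reconstruction tools emit. Level 2
COBRA-notes dialects are auto-detected on read. Serialization is
deterministic (sorted ids) so written files diff cleanly.

A two-table TSV fixture format and a TSV medium format are provided for
hand-written test networks and medium definitions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import libsbml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    format_formula,
    gpr_genes,
    parse_formula,
    parse_gpr,
)

__all__ = [
    "MediumSpec",
    "read_sbml",
    "write_sbml",
    "read_tabular_model",
    "write_tabular_model",
    "read_medium",
    "write_medium",
]

log = logging.getLogger("heterogem.io")


@dataclass
class MediumSpec:
    """Exchange-reaction uptake caps encoding a growth medium.

    ``uptake`` maps exchange id → maximum uptake rate (≥ 0,
    mmol·gDCW⁻¹·h⁻¹); exchanges absent from the map are closed for uptake
    when the medium is applied. ``secretion`` optionally caps secretion.
    """

    uptake: dict[str, float] = field(default_factory=dict)
    secretion: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for table in (self.uptake, self.secretion):
            for rid, rate in table.items():
                if rate < 0:
                    raise ValueError(f"negative rate {rate} for {rid}")


# ---------------------------------------------------------------------------
# SBML


def _sanitize(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", sid)


def write_sbml(model: MetabolicModel, path) -> None:
    """Write an SBML L3V1 + fbc v2 document with deterministic ordering."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted(model.compartments):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met_id in sorted(model.metabolites):
        met = model.metabolites[met_id]
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sanitize(met_id))
        sp.setName(met.name or met_id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula) or "X0")

    # shared bound parameters, one per distinct value
    bound_values = sorted(
        {r.lower_bound for r in model.reactions.values()}
        | {r.upper_bound for r in model.reactions.values()}
    )
    bound_ids = {}
    for value in bound_values:
        pid = "bnd_" + _sanitize(repr(value).replace("-", "minus_").replace(".", "_"))
        bound_ids[value] = pid
        par = sbml_model.createParameter()
        par.setId(pid)
        par.setValue(float(value))
        par.setConstant(True)

    genes = sorted(model.genes)
    for gene in genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sanitize(gene))
        gp.setLabel(gene)

    for rxn_id in sorted(model.reactions):
        rxn = model.reactions[rxn_id]
        sr = sbml_model.createReaction()
        sr.setId("R_" + _sanitize(rxn_id))
        sr.setName(rxn.name or rxn_id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        notes = [f"kind: {rxn.kind}"]
        if rxn.subsystem:
            notes.append(f"subsystem: {rxn.subsystem}")
        sr.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            + "".join(f"<p>{n}</p>" for n in notes)
            + "</body>"
        )
        for met_id in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[met_id]
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sanitize(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_ids[rxn.lower_bound])
        rplug.setUpperFluxBound(bound_ids[rxn.upper_bound])
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            # resolve tokens as gene-product ids; never auto-create products
            gpa.setAssociation(_gpr_to_fbc_string(rxn.gpr), True, False)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sanitize(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _gpr_to_fbc_string(tree) -> str:
    if isinstance(tree, str):
        return "G_" + _sanitize(tree)
    op = f" {tree[0]} "
    return "(" + op.join(_gpr_to_fbc_string(c) for c in tree[1:]) + ")"


def read_sbml(path) -> MetabolicModel:
    """Read an SBML model (L3+fbc, or L2 with COBRA notes, auto-detected)."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValueError(f"malformed SBML in {path}: {msgs[:3]}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"no model element in {path}")
    model = MetabolicModel(sbml_model.getId() or "model")
    mplug = sbml_model.getPlugin("fbc")

    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        met_id = _strip_prefix(sp.getId(), "M_")
        charge = None
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                text = splug.getChemicalFormula()
                formula = parse_formula(text) if text and text != "X0" else {}
        notes = sp.getNotesString() or ""
        if charge is None:
            m = re.search(r"CHARGE:\s*(-?\d+)", notes)
            if m:
                charge = int(m.group(1))
        if formula is None:
            m = re.search(r"FORMULA:\s*([A-Za-z0-9]+)", notes)
            if m:
                formula = parse_formula(m.group(1))
        if charge is None and formula is None:
            log.warning("species %s lacks charge and formula; unauditable", met_id)
        model.add_metabolite(
            Metabolite(
                id=met_id,
                name=sp.getName() or met_id,
                compartment=sp.getCompartment() or "c",
                formula=formula,
                charge=charge,
            )
        )

    parameters = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        rxn_id = _strip_prefix(sr.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()

        lb = ub = None
        rplug = sr.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = parameters.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = parameters.get(rplug.getUpperFluxBound())
        kl = sr.getKineticLaw()
        if (lb is None or ub is None) and kl is not None:
            for j in range(kl.getNumParameters()):
                par = kl.getParameter(j)
                if par.getId() == "LOWER_BOUND" and lb is None:
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND" and ub is None:
                    ub = par.getValue()
        if lb is None or ub is None:
            log.warning(
                "reaction %s lacks bounds; substituting defaults from the "
                "reversible flag",
                rxn_id,
            )
            lb = -DEFAULT_BOUND if sr.getReversible() else 0.0 if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub

        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            gpr = _fbc_association_to_tree(assoc, gene_labels)
        if gpr is None:
            m = re.search(r"GENE_ASSOCIATION:\s*([^<]+)", sr.getNotesString() or "")
            if m and m.group(1).strip():
                gpr = parse_gpr(m.group(1).strip())

        notes = sr.getNotesString() or ""
        m = re.search(r"kind:\s*(\w+)", notes)
        kind = m.group(1) if m else _infer_kind(rxn_id, stoich, model)
        m = re.search(r"subsystem:\s*([^<]+)", notes)
        subsystem = m.group(1).strip() if m else ""

        model.add_reaction(
            Reaction(
                id=rxn_id,
                name=sr.getName() or rxn_id,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
                subsystem=subsystem,
                kind=kind,
            )
        )

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            rid = _strip_prefix(obj.getFluxObjective(0).getReaction(), "R_")
            if rid in model.reactions:
                model.objective_id = rid
    return model


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _fbc_association_to_tree(assoc, gene_labels):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        return gene_labels.get(gid, _strip_prefix(gid, "G_"))
    op = "and" if assoc.isFbcAnd() else "or"
    children = [
        _fbc_association_to_tree(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    return (op, *children)


def _infer_kind(rxn_id: str, stoich: dict, model: MetabolicModel) -> str:
    """Exchange detection: single extracellular metabolite, or EX_ prefix."""
    if rxn_id.startswith("DM_"):
        return "demand"
    if rxn_id.startswith("SK_"):
        return "sink"
    mets = [m for m, c in stoich.items() if abs(c) > 1e-12]
    if rxn_id.startswith("EX_"):
        return "exchange"
    if len(mets) == 1 and model.metabolites[mets[0]].compartment == "e":
        return "exchange"
    return "internal"


# ---------------------------------------------------------------------------
# Tabular fixture format: one file, two TSV tables introduced by
# "[metabolites]" and "[reactions]" section headers.

_ARROWS = {"<=>": (-DEFAULT_BOUND, DEFAULT_BOUND), "-->": (0.0, DEFAULT_BOUND),
           "<--": (-DEFAULT_BOUND, 0.0)}


def parse_equation(equation: str) -> tuple[dict[str, float], tuple[float, float]]:
    """Parse ``a A + b B <=> c C`` into a stoichiometry map + arrow bounds.

    Arrow dialects: ``<=>`` reversible, ``-->`` forward, ``<--`` reverse
    (bounds (-1000, 0)). Either side may be empty (boundary reactions).
    """
    arrow = None
    for a in _ARROWS:
        if a in equation:
            arrow = a
            break
    if arrow is None:
        raise ValueError(f"no arrow in equation {equation!r}")
    lhs, rhs = equation.split(arrow)
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            else:
                raise ValueError(f"unparseable term {term!r} in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    return stoich, _ARROWS[arrow]


def read_tabular_model(path) -> MetabolicModel:
    """Read the two-table TSV fixture format."""
    model = MetabolicModel("model")
    section = None
    header: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.strip() in ("[metabolites]", "[reactions]"):
                section = line.strip()[1:-1]
                header = []
                continue
            if not header:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            if section == "metabolites":
                formula = row.get("formula", "")
                charge = row.get("charge", "")
                model.add_metabolite(
                    Metabolite(
                        id=row["id"],
                        name=row.get("name", row["id"]),
                        compartment=row.get("compartment", "c"),
                        formula=parse_formula(formula) if formula else None,
                        charge=int(charge) if charge not in ("", "NA") else None,
                    )
                )
            elif section == "reactions":
                stoich, arrow_bounds = parse_equation(row["equation"])
                unknown = [m for m in stoich if m not in model.metabolites]
                if unknown:
                    raise ValueError(
                        f"reaction {row['id']}: unknown metabolite(s) {unknown}"
                    )
                lb = float(row["lb"]) if row.get("lb") else arrow_bounds[0]
                ub = float(row["ub"]) if row.get("ub") else arrow_bounds[1]
                model.add_reaction(
                    Reaction(
                        id=row["id"],
                        name=row.get("name", row["id"]),
                        stoichiometry=stoich,
                        lower_bound=lb,
                        upper_bound=ub,
                        gpr=parse_gpr(row["gpr"]) if row.get("gpr") else None,
                        subsystem=row.get("subsystem", ""),
                        kind=row.get("kind") or "internal",
                    )
                )
            else:
                raise ValueError(f"data before section header in {path}")
    if "BIOMASS" in model.reactions:
        model.objective_id = "BIOMASS"
    return model


def format_equation(rxn: Reaction) -> str:
    def side(sign):
        terms = []
        for met in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[met]
            if sign * coeff > 0:
                c = abs(coeff)
                terms.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(terms)

    arrow = "<=>" if rxn.lower_bound < 0 < rxn.upper_bound else (
        "<--" if rxn.upper_bound <= 0 else "-->"
    )
    return f"{side(-1)} {arrow} {side(1)}"


def write_tabular_model(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("[metabolites]\n")
        fh.write("id\tname\tcompartment\tformula\tcharge\n")
        for met_id in sorted(model.metabolites):
            m = model.metabolites[met_id]
            fh.write(
                "\t".join(
                    [
                        m.id,
                        m.name,
                        m.compartment,
                        m.formula_string(),
                        "" if m.charge is None else str(m.charge),
                    ]
                )
                + "\n"
            )
        fh.write("[reactions]\n")
        fh.write("id\tname\tequation\tlb\tub\tgpr\tkind\tsubsystem\n")
        for rxn_id in sorted(model.reactions):
            r = model.reactions[rxn_id]
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        format_equation(r),
                        f"{r.lower_bound:g}",
                        f"{r.upper_bound:g}",
                        r.gpr_string(),
                        r.kind,
                        r.subsystem,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Medium files: TSV of exchange id → uptake cap (optional secretion cap).


def read_medium(path) -> MediumSpec:
    uptake: dict[str, float] = {}
    secretion: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith(
                "exchange"
            ):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            rid, rate = fields[0], float(fields[1])
            if rate < 0:
                raise ValueError(f"negative uptake rate {rate} for {rid}")
            uptake[rid] = rate
            if len(fields) > 2 and fields[2] != "":
                cap = float(fields[2])
                if cap < 0:
                    raise ValueError(f"negative secretion cap {cap} for {rid}")
                secretion[rid] = cap
    return MediumSpec(uptake=uptake, secretion=secretion)


def write_medium(medium: MediumSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("exchange_id\tuptake_cap\tsecretion_cap\n")
        for rid in sorted(medium.uptake):
            sec = medium.secretion.get(rid, "")
            fh.write(f"{rid}\t{medium.uptake[rid]:g}\t{sec if sec == '' else f'{sec:g}'}\n")
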