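"""In-memory representation of a constraint-based metabolic model.

A :class:`MetabolicModel` is the stoichiometric system S·v = 0 with box
bounds on every reaction flux, plus the elemental/charge bookkeeping needed
for curation: each :class:`Metabolite` carries a Hill-style formula (as an
element → count map, with unknown tokens such as ``R`` or ``X`` kept as
opaque pseudo-elements) and an integer charge, so any internal reaction can
be audited for mass and charge balance.

Pseudo-reactions — biomass, maintenance (ATPM), macromolecule synthesis,
and boundary reactions — are exempt from balance audits by their ``kind``
flag, mirroring standard practice in genome-scale modeling.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "parse_formula",
    "format_formula",
    "parse_gpr",
    "gpr_genes",
    "check_mass_balance",
    "check_charge_balance",
    "merge_metabolites",
    "add_boundary_reaction",
    "model_stats",
]

#: Default magnitude used for "unbounded" fluxes, mmol·gDCW⁻¹·h⁻¹.
DEFAULT_BOUND = 1000.0

#: Tolerance used when comparing stoichiometries (duplicate detection) and
#: when deciding whether a balance residual is real or float noise.
STOICH_TOL = 1e-9

REACTION_KINDS = ("internal", "exchange", "demand", "sink", "biomass", "maintenance")

#: Kinds exempt from mass/charge balance audits.
BALANCE_EXEMPT_KINDS = ("exchange", "demand", "sink", "biomass", "maintenance")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element → count map.

    One- or two-letter element symbols with optional integer counts;
    unknown symbols (R-groups, X) are kept as opaque pseudo-elements.
    Raises ``ValueError`` on unparseable input.
    """
    if formula is None:
        raise ValueError("formula is None")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        element = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Canonical (Hill order: C, H, then alphabetical) formula string."""
    if not counts:
        return ""
    keys = sorted(counts)
    ordered = [k for k in ("C", "H") if k in counts] + [
        k for k in keys if k not in ("C", "H")
    ]
    parts = []
    for k in ordered:
        n = counts[k]
        if n == 0:
            continue
        parts.append(k if n == 1 else f"{k}{n}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Gene-protein-reaction rules: a boolean AND/OR tree over gene ids,
# represented as nested tuples ("and"|"or", child, child, ...) with bare
# gene-id strings at the leaves.

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str):
    """Parse a GPR string like ``(g1 and g2) or g3`` into a tuple tree.

    Returns ``None`` for empty rules. ``and`` binds tighter than ``or``.
    """
    if rule is None:
        return None
    tokens = _GPR_TOKEN.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", *terms)

    def parse_and():
        nonlocal pos
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", *terms)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ValueError(f"truncated GPR rule {rule!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule {rule!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token {tok!r} in GPR rule {rule!r}")
        pos += 1
        return tok

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule {rule!r}")
    return tree


def gpr_to_string(tree) -> str:
    if tree is None:
        return ""
    if isinstance(tree, str):
        return tree
    op = tree[0]
    parts = []
    for child in tree[1:]:
        s = gpr_to_string(child)
        if isinstance(child, tuple) and child[0] != op:
            s = f"({s})"
        parts.append(s)
    return f" {op} ".join(parts)


def gpr_genes(tree) -> set[str]:
    """Set of gene ids appearing in a GPR tree."""
    if tree is None:
        return set()
    if isinstance(tree, str):
        return {tree}
    out: set[str] = set()
    for child in tree[1:]:
        out |= gpr_genes(child)
    return out


# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol → non-negative count; ``None`` means
    unknown (the metabolite is then unauditable for mass balance).
    ``charge`` is the signed formal charge, ``None`` if unknown.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None

    def formula_string(self) -> str:
        return format_formula(self.formula) if self.formula is not None else ""

    def copy(self) -> "Metabolite":
        return copy.deepcopy(self)


@dataclass
class Reaction:
    """A (possibly pseudo-) reaction with stoichiometry and flux bounds.

    Negative stoichiometric coefficients are substrates, positive are
    products. Bounds are in mmol·gDCW⁻¹·h⁻¹ (h⁻¹ for the biomass flux).
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: tuple | str | None = None
    subsystem: str = ""
    kind: str = "internal"

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    @property
    def boundary(self) -> bool:
        return self.kind in ("exchange", "demand", "sink")

    def gpr_string(self) -> str:
        return gpr_to_string(self.gpr)

    def normalized_stoichiometry(self) -> tuple:
        """Hashable canonical form used for duplicate-reaction detection.

        Coefficients are rounded to the comparison tolerance so float noise
        does not defeat duplicate detection; an overall sign flip (the same
        chemistry written in the opposite direction) maps to the same key.
        """
        items = tuple(
            sorted(
                (m, round(c / STOICH_TOL) * STOICH_TOL)
                for m, c in self.stoichiometry.items()
                if abs(c) > STOICH_TOL
            )
        )
        if not items:
            return items
        flipped = tuple(sorted((m, -c) for m, c in items))
        return min(items, flipped)

    def copy(self) -> "Reaction":
        return copy.deepcopy(self)


class MetabolicModel:
    """Metabolites, reactions, genes and an objective: the system S·v = 0."""

    def __init__(self, model_id: str = "model"):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_id: str | None = None

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise KeyError(
                f"reaction {rxn.id} references unknown metabolites: {missing}"
            )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    def set_objective(self, rxn_id: str) -> None:
        if rxn_id not in self.reactions:
            raise KeyError(f"objective reaction {rxn_id!r} not in model")
        self.objective_id = rxn_id

    # -- views ---------------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def boundary_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.boundary]

    def validate(self) -> None:
        """Raise on violated structural invariants."""
        for rid, rxn in self.reactions.items():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValueError(f"reaction {rid} references missing {met}")
            if not rxn.stoichiometry and not rxn.boundary:
                raise ValueError(f"internal reaction {rid} has empty stoichiometry")
            if rxn.kind == "exchange":
                mets = [m for m, c in rxn.stoichiometry.items() if abs(c) > STOICH_TOL]
                if len(mets) != 1:
                    raise ValueError(f"exchange {rid} must touch exactly one metabolite")
                met = self.metabolites[mets[0]]
                if met.compartment != "e":
                    raise ValueError(f"exchange {rid} metabolite not extracellular")
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValueError(f"objective {self.objective_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def __repr__(self):
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# Balance audits


def check_mass_balance(
    reaction: Reaction, metabolite_table: dict[str, Metabolite]
) -> dict[str, float]:
    """Net elemental imbalance of a reaction: element → Σ(coeff × count).

    Empty map ⇔ balanced. Boundary and other pseudo-reactions are exempt and
    return ``{"exempt": 0.0}``; a missing formula on an internal reaction's
    metabolite makes the reaction unauditable (``{"unauditable": ...}``) —
    never silently reported as balanced.
    """
    if reaction.kind in BALANCE_EXEMPT_KINDS:
        return {"exempt": 0.0}
    net: dict[str, float] = {}
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolite_table[met_id]
        if met.formula is None:
            return {"unauditable": float("nan")}
        for element, count in met.formula.items():
            net[element] = net.get(element, 0.0) + coeff * count
    return {e: v for e, v in net.items() if abs(v) > STOICH_TOL * 10}


def check_charge_balance(
    reaction: Reaction, metabolite_table: dict[str, Metabolite]
) -> float | None:
    """Net charge imbalance; 0 ⇔ balanced, ``None`` for exempt/unauditable."""
    if reaction.kind in BALANCE_EXEMPT_KINDS:
        return None
    net = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolite_table[met_id]
        if met.charge is None:
            return None
        net += coeff * met.charge
    return 0.0 if abs(net) <= STOICH_TOL * 10 else net


# ---------------------------------------------------------------------------
# Editing operations


def merge_metabolites(
    model: MetabolicModel, keep_id: str, drop_id: str
) -> MetabolicModel:
    """Rewrite every occurrence of ``drop_id`` to ``keep_id`` (in place).

    Coefficients landing on the same metabolite are summed; reactions that
    become stoichiometrically identical to an existing reaction are removed
    as duplicates; ``drop_id`` is deleted. Merging across compartments is an
    error. Returns the model for chaining.
    """
    if keep_id == drop_id:
        return model
    keep = model.metabolites[keep_id]
    drop = model.metabolites[drop_id]
    if keep.compartment != drop.compartment:
        raise ValueError(
            f"cannot merge {drop_id} into {keep_id}: different compartments"
        )
    touched = []
    for rxn in model.reactions.values():
        if drop_id in rxn.stoichiometry:
            coeff = rxn.stoichiometry.pop(drop_id)
            rxn.stoichiometry[keep_id] = rxn.stoichiometry.get(keep_id, 0.0) + coeff
            if abs(rxn.stoichiometry[keep_id]) <= STOICH_TOL:
                del rxn.stoichiometry[keep_id]
            touched.append(rxn.id)
    # collapse reactions that are now duplicates of an untouched one
    seen: dict[tuple, str] = {}
    for rid, rxn in list(model.reactions.items()):
        key = rxn.normalized_stoichiometry()
        if key in seen and (rid in touched or seen[key] in touched):
            drop_rid = rid if rid in touched else seen[key]
            model.remove_reaction(drop_rid)
            if drop_rid == seen[key]:
                seen[key] = rid
        else:
            seen.setdefault(key, rid)
    del model.metabolites[drop_id]
    return model


_BOUNDARY_PREFIX = {"exchange": "EX_", "demand": "DM_", "sink": "SK_"}
_BOUNDARY_BOUNDS = {
    "exchange": (-DEFAULT_BOUND, DEFAULT_BOUND),
    "demand": (0.0, DEFAULT_BOUND),
    "sink": (-DEFAULT_BOUND, DEFAULT_BOUND),
}


def add_boundary_reaction(
    model: MetabolicModel, metabolite_id: str, kind: str = "exchange"
) -> Reaction:
    """Add an EX_/DM_/SK_ boundary reaction draining ``metabolite_id``.

    Exchanges require an extracellular metabolite; a second boundary
    reaction of the same kind for the same metabolite is an error.
    """
    if kind not in _BOUNDARY_PREFIX:
        raise ValueError(f"boundary kind must be exchange/demand/sink, got {kind!r}")
    met = model.metabolites[metabolite_id]
    if kind == "exchange" and met.compartment != "e":
        raise ValueError(
            f"exchange reactions require compartment 'e'; {metabolite_id} is in "
            f"{met.compartment!r}"
        )
    for rxn in model.reactions.values():
        if rxn.kind == kind and rxn.stoichiometry.get(metabolite_id):
            raise ValueError(
                f"{kind} reaction for {metabolite_id} already present ({rxn.id})"
            )
    rid = _BOUNDARY_PREFIX[kind] + metabolite_id
    lb, ub = _BOUNDARY_BOUNDS[kind]
    rxn = Reaction(
        id=rid,
        name=f"{kind} for {met.name or metabolite_id}",
        stoichiometry={metabolite_id: -1.0},
        lower_bound=lb,
        upper_bound=ub,
        kind=kind,
    )
    model.add_reaction(rxn)
    return rxn


def model_stats(model: MetabolicModel) -> dict[str, int]:
    """Counts of genes, reactions, reactions without GPR, and metabolites."""
    without_gpr = sum(1 for r in model.reactions.values() if r.gpr is None)
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "reactions_without_gpr": without_gpr,
        "metabolites": len(model.metabolites),
    }
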