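"""Curation diagnostics for genome-scale models.

Re-implements the quality checks that drive manual curation of draft
reconstructions: mass/charge balance audits, duplicate metabolites and
reactions, dead-end metabolites, thermodynamically infeasible loops
(reactions able to carry flux with every boundary closed), gene-set
comparison across reconstructions, and a consolidated report.

The loop test is the operative check inside loop-detection tool suites:
close all exchange/demand/sink reactions and ask, per internal reaction,
whether any nonzero steady-state flux remains feasible. Any such flux is a
pure internal circulation, which violates thermodynamics and can leak
arbitrary ATP/NAD(P)H into FBA solutions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from .lp import DEFAULT_BACKEND, ZERO_TOL, _build_system
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    check_charge_balance,
    check_mass_balance,
)

__all__ = [
    "QCReport",
    "GeneSetComparison",
    "detect_duplicate_metabolites",
    "detect_duplicate_reactions",
    "detect_dead_ends",
    "detect_loops",
    "compare_gene_sets",
    "qc_report",
]

_STEREO_PREFIX = re.compile(r"^\(?[rsdl](,[rsdl])?\)?-")


def normalize_name(name: str) -> str:
    """Duplicate-matching name normalization.

    Case-fold, drop whitespace, and strip leading stereo-descriptor
    prefixes ("S-", "(S)-", "S,S-", ...) so that e.g. "S-acetoin" and
    "(S)-acetoin" compare equal. The rule is deliberately explicit — the
    groups it produces are candidates for merging, not proof of identity.
    """
    s = re.sub(r"\s+", "", name.casefold())
    while True:
        stripped = _STEREO_PREFIX.sub("", s)
        if stripped == s:
            return s
        s = stripped


def detect_duplicate_metabolites(model: MetabolicModel) -> list[list[str]]:
    """Groups (size ≥ 2) of same-compartment metabolites with identical
    formula and charge and normalization-equivalent names.

    Metabolites lacking a formula or charge are excluded from grouping
    (they show up in the QC report as unauditable instead).
    """
    buckets: dict[tuple, list[str]] = {}
    for met in model.metabolites.values():
        if met.formula is None or met.charge is None:
            continue
        key = (
            met.compartment,
            tuple(sorted(met.formula.items())),
            met.charge,
            normalize_name(met.name or met.id),
        )
        buckets.setdefault(key, []).append(met.id)
    return sorted(sorted(g) for g in buckets.values() if len(g) >= 2)


def detect_duplicate_reactions(model: MetabolicModel) -> list[tuple[str, str]]:
    """Pairs of reactions with identical normalized stoichiometry."""
    buckets: dict[tuple, list[str]] = {}
    for rxn in model.reactions.values():
        buckets.setdefault(rxn.normalized_stoichiometry(), []).append(rxn.id)
    pairs = []
    for group in buckets.values():
        if len(group) >= 2:
            group = sorted(group)
            pairs.extend(
                (group[i], group[j])
                for i in range(len(group))
                for j in range(i + 1, len(group))
            )
    return sorted(pairs)


def detect_dead_ends(model: MetabolicModel) -> list[str]:
    """Metabolites only produced or only consumed.

    A reversible reaction counts as both a producer and a consumer of all
    its participants; blocked reactions (both bounds zero) are ignored, as
    are metabolites touching no active reaction.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    active: set[str] = set()
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        if not fwd and not rev:
            continue
        for met, coeff in rxn.stoichiometry.items():
            if abs(coeff) < 1e-12:
                continue
            active.add(met)
            if (coeff > 0 and fwd) or (coeff < 0 and rev):
                produced.add(met)
            if (coeff < 0 and fwd) or (coeff > 0 and rev):
                consumed.add(met)
    return sorted(m for m in active if (m in produced) != (m in consumed))


def detect_loops(model: MetabolicModel, tol: float = ZERO_TOL) -> list[str]:
    """Internal reactions able to carry flux with all boundaries closed.

    Clones the model, sets every exchange/demand/sink bound to (0, 0), and
    runs a pure-feasibility FVA (zero objective) over the internal
    reactions; any reaction whose range escapes ±``tol`` participates in a
    stoichiometrically balanced internal cycle. The result is by
    construction invariant to medium changes.
    """
    work = model.copy()
    for rxn in work.reactions.values():
        if rxn.boundary:
            rxn.lower_bound = rxn.upper_bound = 0.0
        else:
            # forced-throughput bounds (e.g. a maintenance floor) would make
            # the closed system infeasible; the loop question is about
            # admissible directions, so relax each range to include zero
            rxn.lower_bound = min(rxn.lower_bound, 0.0)
            rxn.upper_bound = max(rxn.upper_bound, 0.0)
    rxn_ids, S, bounds = _build_system(work)
    b_eq = np.zeros(S.shape[0])
    n = len(rxn_ids)
    flagged = []
    for j, rid in enumerate(rxn_ids):
        if work.reactions[rid].boundary:
            continue
        lb, ub = bounds[j]
        if lb == 0.0 and ub == 0.0:
            continue
        c = np.zeros(n)
        c[j] = 1.0
        _, _, lo = DEFAULT_BACKEND.solve(c, S, b_eq, bounds)
        c[j] = -1.0
        _, _, hi = DEFAULT_BACKEND.solve(c, S, b_eq, bounds)
        if (lo is not None and abs(lo) > tol) or (
            hi is not None and abs(hi) > tol
        ):
            flagged.append(rid)
    return sorted(flagged)


@dataclass
class GeneSetComparison:
    """Inclusion/exclusion lattice over named gene sets.

    ``regions`` maps a tuple of model names (exact membership region of the
    Venn lattice) to its gene count; ``unique`` lists per-model exclusive
    genes; ``dropped`` counts ids discarded by the mapping table.
    """

    regions: dict[tuple[str, ...], int]
    unique: dict[str, list[str]]
    dropped: dict[str, int]


def compare_gene_sets(models, mapping: dict[str, str] | None = None) -> GeneSetComparison:
    """Region counts over the 2ⁿ−1 Venn regions of n models' gene sets.

    ``models`` is a mapping or sequence of (name, model-or-gene-set) pairs;
    duplicate names are an error. If an id-mapping table is given
    (old_locus_tag/protein_id → locus_tag), ids are translated first and
    unmapped ids are dropped and counted per model.
    """
    pairs = list(models.items()) if isinstance(models, dict) else list(models)
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names in {names}")
    sets: dict[str, set[str]] = {}
    dropped: dict[str, int] = {}
    for name, obj in pairs:
        genes = obj.genes if isinstance(obj, MetabolicModel) else set(obj)
        if mapping is not None:
            mapped = {mapping[g] for g in genes if g in mapping}
            dropped[name] = len([g for g in genes if g not in mapping])
            genes = mapped
        else:
            dropped[name] = 0
        sets[name] = set(genes)
    universe = set().union(*sets.values()) if sets else set()
    regions: dict[tuple[str, ...], int] = {}
    for gene in universe:
        region = tuple(sorted(n for n in names if gene in sets[n]))
        regions[region] = regions.get(region, 0) + 1
    unique = {
        n: sorted(g for g in sets[n] if all(g not in sets[o] for o in names if o != n))
        for n in names
    }
    return GeneSetComparison(regions=regions, unique=unique, dropped=dropped)


@dataclass
class QCReport:
    """Consolidated curation diagnostics; counts equal list lengths."""

    mass_unbalanced: list[str] = field(default_factory=list)
    charge_unbalanced: list[str] = field(default_factory=list)
    unauditable: list[str] = field(default_factory=list)
    duplicate_metabolite_groups: list[list[str]] = field(default_factory=list)
    duplicate_reaction_pairs: list[tuple[str, str]] = field(default_factory=list)
    dead_end_metabolites: list[str] = field(default_factory=list)
    loop_reactions: list[str] = field(default_factory=list)
    reactions_without_gpr: list[str] = field(default_factory=list)
    reactions_at_default_bounds: list[str] = field(default_factory=list)

    #: Categories that represent defects (as opposed to informational lists).
    DEFECT_FIELDS = (
        "mass_unbalanced",
        "charge_unbalanced",
        "duplicate_metabolite_groups",
        "duplicate_reaction_pairs",
        "dead_end_metabolites",
        "loop_reactions",
    )

    def counts(self) -> dict[str, int]:
        return {
            name: len(getattr(self, name))
            for name in (
                "mass_unbalanced",
                "charge_unbalanced",
                "unauditable",
                "duplicate_metabolite_groups",
                "duplicate_reaction_pairs",
                "dead_end_metabolites",
                "loop_reactions",
                "reactions_without_gpr",
                "reactions_at_default_bounds",
            )
        }

    def defect_counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in self.DEFECT_FIELDS}

    def clean(self) -> bool:
        return all(v == 0 for v in self.defect_counts().values())

    def to_json(self, path=None) -> str:
        payload = {
            "counts": self.counts(),
            **{
                name: getattr(self, name)
                for name in self.counts()
            },
        }
        text = json.dumps(payload, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def qc_report(model: MetabolicModel, check_loops: bool = True) -> QCReport:
    """Run every diagnostic and aggregate the findings (sorted ids)."""
    mass, charge, unauditable = [], [], []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        imbalance = check_mass_balance(rxn, model.metabolites)
        if "exempt" in imbalance:
            continue
        if "unauditable" in imbalance:
            unauditable.append(rid)
            continue
        if imbalance:
            mass.append(rid)
        q = check_charge_balance(rxn, model.metabolites)
        if q is not None and q != 0.0:
            charge.append(rid)
    return QCReport(
        mass_unbalanced=mass,
        charge_unbalanced=charge,
        unauditable=unauditable,
        duplicate_metabolite_groups=detect_duplicate_metabolites(model),
        duplicate_reaction_pairs=detect_duplicate_reactions(model),
        dead_end_metabolites=detect_dead_ends(model),
        loop_reactions=detect_loops(model) if check_loops else [],
        reactions_without_gpr=sorted(
            r.id for r in model.reactions.values() if r.gpr is None
        ),
        reactions_at_default_bounds=sorted(
            r.id
            for r in model.reactions.values()
            if r.lower_bound == -DEFAULT_BOUND and r.upper_bound == DEFAULT_BOUND
        ),
    )
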