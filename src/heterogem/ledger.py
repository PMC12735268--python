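"""Transactional, replayable model edits.

Every manual-curation step — re-bounding a reaction, blocking a gap-filled
orphan, merging duplicate metabolites, adding a maintenance or boundary
reaction — is recorded as an :class:`Edit` in an ordered :class:`EditLedger`
so the whole curation is data: deterministic to replay, diffable as TSV, and
auditable (each edit carries a free-text rationale and optional citation).

``apply_ledger`` is transactional: the edits are applied to a copy and the
untouched input model is returned unchanged if any edit fails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    add_boundary_reaction,
    merge_metabolites,
    parse_formula,
)

__all__ = ["Edit", "EditLedger", "apply_ledger", "read_ledger", "write_ledger"]

EDIT_KINDS = (
    "set_bounds",
    "add_reaction",
    "remove_reaction",
    "block_reaction",
    "merge_metabolites",
    "add_exchange",
    "add_demand",
    "set_objective",
    "set_biomass",
)


@dataclass
class Edit:
    """One ledger record: what was changed, on what, and why."""

    kind: str
    target: str = ""
    payload: dict = field(default_factory=dict)
    rationale: str = ""
    citation: str = ""

    def __post_init__(self):
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass
class EditLedger:
    edits: list[Edit] = field(default_factory=list)

    def append(self, edit: Edit) -> "EditLedger":
        self.edits.append(edit)
        return self

    def __len__(self):
        return len(self.edits)

    def __iter__(self):
        return iter(self.edits)


def _apply_edit(model: MetabolicModel, edit: Edit) -> dict:
    """Apply one edit in place; returns a before/after report entry."""
    before: object = None
    if edit.kind == "set_bounds":
        rxn = model.reactions[edit.target]
        before = (rxn.lower_bound, rxn.upper_bound)
        rxn.lower_bound = float(edit.payload["lower_bound"])
        rxn.upper_bound = float(edit.payload["upper_bound"])
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(f"set_bounds on {edit.target}: lb > ub")
        after = (rxn.lower_bound, rxn.upper_bound)
    elif edit.kind == "block_reaction":
        rxn = model.reactions[edit.target]
        before = (rxn.lower_bound, rxn.upper_bound)
        rxn.lower_bound = rxn.upper_bound = 0.0
        after = (0.0, 0.0)
    elif edit.kind == "remove_reaction":
        before = edit.target
        model.remove_reaction(edit.target)
        after = None
    elif edit.kind == "add_reaction":
        p = dict(edit.payload)
        for met_spec in p.pop("new_metabolites", []):
            spec = dict(met_spec)
            formula = spec.get("formula")
            if isinstance(formula, str):
                spec["formula"] = parse_formula(formula) if formula else None
            if spec["id"] not in model.metabolites:
                model.add_metabolite(Metabolite(**spec))
        rxn = Reaction(id=edit.target, **p)
        model.add_reaction(rxn)
        before, after = None, edit.target
    elif edit.kind == "merge_metabolites":
        before = edit.payload["drop_id"]
        merge_metabolites(model, edit.target, edit.payload["drop_id"])
        after = edit.target
    elif edit.kind in ("add_exchange", "add_demand"):
        kind = "exchange" if edit.kind == "add_exchange" else "demand"
        rxn = add_boundary_reaction(model, edit.target, kind)
        before, after = None, rxn.id
    elif edit.kind == "set_objective":
        before = model.objective_id
        model.set_objective(edit.target)
        after = edit.target
    elif edit.kind == "set_biomass":
        rxn = model.reactions[edit.target]
        before = dict(rxn.stoichiometry)
        rxn.stoichiometry = {
            m: float(c) for m, c in edit.payload["stoichiometry"].items()
        }
        missing = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if missing:
            raise KeyError(f"set_biomass references unknown metabolites {missing}")
        after = dict(rxn.stoichiometry)
    else:  # pragma: no cover - guarded by Edit.__post_init__
        raise ValueError(edit.kind)
    return {"kind": edit.kind, "target": edit.target, "before": before, "after": after}


def apply_ledger(
    model: MetabolicModel, ledger: EditLedger
) -> tuple[MetabolicModel, list[dict]]:
    """Replay a ledger on a copy of ``model``; transactional.

    Returns ``(edited_model, report)``; on any failure raises after
    discarding all partial work, so the caller's model is never mutated.
    The raised error names the offending edit index.
    """
    work = model.copy()
    report = []
    for i, edit in enumerate(ledger):
        try:
            report.append(_apply_edit(work, edit))
        except Exception as exc:
            raise type(exc)(f"ledger edit {i} ({edit.kind} {edit.target}): {exc}") from exc
    return work, report


# ---------------------------------------------------------------------------
# TSV serialization: one record per edit; payload as compact JSON so the
# file stays a flat, diffable table.

_HEADER = ["kind", "target", "payload", "rationale", "citation"]


def write_ledger(ledger: EditLedger, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for e in ledger:
            payload = json.dumps(e.payload, sort_keys=True) if e.payload else ""
            fh.write(
                "\t".join([e.kind, e.target, payload, e.rationale, e.citation]) + "\n"
            )


def read_ledger(path) -> EditLedger:
    ledger = EditLedger()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"unexpected ledger header {header}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            fields += [""] * (len(_HEADER) - len(fields))
            kind, target, payload, rationale, citation = fields[:5]
            ledger.append(
                Edit(
                    kind=kind,
                    target=target,
                    payload=json.loads(payload) if payload else {},
                    rationale=rationale,
                    citation=citation,
                )
            )
    return ledger
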