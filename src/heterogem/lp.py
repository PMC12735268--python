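"""Flux balance analysis primitives: FBA, parsimonious FBA, and FVA.

All three solve linear programs over the steady-state system S·v = 0 with
box bounds. FBA maximizes the objective reaction's flux. pFBA is the
standard two-stage formulation: fix the objective at its optimum (within
tolerance), then minimize total absolute flux Σ|v| via forward/reverse
splitting. FVA minimizes and maximizes each reaction's flux subject to the
objective being at least a fraction of its optimum (2 LPs per reaction).

The LP solver sits behind a single small backend contract so solvers are
swappable; the default backend is HiGHS via scipy.optimize.linprog.
Individual fluxes at degenerate alternate optima are solver-dependent;
only objective values, flux totals, and FVA envelopes are well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["FluxSolution", "FVAResult", "fba", "pfba", "fva", "ScipyHighsBackend"]

#: Relative tolerance of optimality assertions.
OPT_TOL = 1e-6

#: Relative slack used when fixing the objective at its optimum in the
#: second-stage problems (pFBA, FVA); much tighter than OPT_TOL so that
#: second-stage results do not exploit the fixing window.
FIX_TOL = 1e-9

#: Fluxes below this magnitude are reported as zero.
ZERO_TOL = 1e-6


class ScipyHighsBackend:
    """LP backend contract: ``solve(c, A_eq, b_eq, bounds) -> (status, x, fun)``.

    Minimizes c·x subject to A_eq·x = b_eq and box bounds.
    Status is one of {"optimal", "infeasible", "unbounded"}.
    """

    _STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}

    def solve(self, c, A_eq, b_eq, bounds):
        res = linprog(
            c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
            options={"presolve": True},
        )
        status = self._STATUS.get(res.status)
        if status is None:
            raise RuntimeError(f"LP solver failure: {res.message}")
        x = res.x if res.status == 0 else None
        fun = res.fun if res.status == 0 else None
        return status, x, fun


DEFAULT_BACKEND = ScipyHighsBackend()


@dataclass
class FluxSolution:
    """Outcome of one FBA/pFBA solve.

    ``objective_value`` is in h⁻¹ for growth objectives, otherwise flux
    units (mmol·gDCW⁻¹·h⁻¹). ``fluxes`` is empty unless status is optimal.
    """

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def total_flux(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())


@dataclass
class FVAResult:
    """Per-reaction feasible flux ranges at a fixed objective fraction."""

    ranges: dict[str, tuple[float, float]]
    fraction: float
    objective_value: float


def _build_system(model: MetabolicModel):
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            data.append(coeff)
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in rxn_ids
    ]
    return rxn_ids, S, bounds


def fba(model: MetabolicModel, backend=None) -> FluxSolution:
    """Maximize the model's objective flux subject to S·v = 0 and bounds."""
    if model.objective_id is None:
        raise ValueError("model has no objective reaction")
    backend = backend or DEFAULT_BACKEND
    rxn_ids, S, bounds = _build_system(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(model.objective_id)] = -1.0  # maximize
    status, x, fun = backend.solve(c, S, np.zeros(S.shape[0]), bounds)
    if status != "optimal":
        return FluxSolution(status=status)
    return FluxSolution(
        status="optimal",
        objective_value=-fun,
        fluxes=dict(zip(rxn_ids, x)),
    )


def pfba(model: MetabolicModel, backend=None) -> FluxSolution:
    """Parsimonious FBA: minimal total |flux| at the FBA optimum.

    The returned ``objective_value`` is the (re-measured) flux of the
    model's objective reaction, equal to the FBA optimum to within
    ``OPT_TOL`` relative.
    """
    backend = backend or DEFAULT_BACKEND
    first = fba(model, backend)
    if not first.optimal:
        return first
    opt = first.objective_value
    rxn_ids, S, bounds = _build_system(model)
    n = len(rxn_ids)
    obj_j = rxn_ids.index(model.objective_id)
    slack = FIX_TOL * max(1.0, abs(opt))
    lb, ub = bounds[obj_j]
    bounds = list(bounds)
    bounds[obj_j] = (max(lb, opt - slack), min(ub, opt + slack))
    # v = f - r with f, r >= 0; minimize sum(f + r)
    m = S.shape[0]
    eye = sparse.identity(n, format="csr")
    A_eq = sparse.vstack(
        [
            sparse.hstack([S, sparse.csr_matrix((m, 2 * n))]),
            sparse.hstack([eye, -eye, eye]),
        ],
        format="csr",
    )
    b_eq = np.zeros(m + n)
    big = max(abs(b) for bb in bounds for b in bb)
    full_bounds = bounds + [(0.0, big)] * (2 * n)
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    status, x, _ = backend.solve(c, A_eq, b_eq, full_bounds)
    if status != "optimal":  # numerically tight; fall back to the FBA point
        return first
    fluxes = dict(zip(rxn_ids, x[:n]))
    return FluxSolution(
        status="optimal", objective_value=fluxes[model.objective_id], fluxes=fluxes
    )


def fva(
    model: MetabolicModel,
    reaction_ids=None,
    fraction: float = 1.0,
    backend=None,
) -> FVAResult:
    """Feasible flux range per reaction at ≥ ``fraction`` × optimum.

    ``fraction`` defaults to 1.0 (ranges at the optimum); must satisfy
    0 < fraction ≤ 1. Propagates infeasibility of the base problem.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    backend = backend or DEFAULT_BACKEND
    first = fba(model, backend)
    if not first.optimal:
        raise RuntimeError(f"FVA base problem is {first.status}")
    opt = first.objective_value
    rxn_ids, S, bounds = _build_system(model)
    if reaction_ids is None:
        reaction_ids = rxn_ids
    obj_j = rxn_ids.index(model.objective_id)
    slack = FIX_TOL * max(1.0, abs(opt))
    target = fraction * opt
    lb, ub = bounds[obj_j]
    bounds = list(bounds)
    bounds[obj_j] = (max(lb, target - slack), ub)
    b_eq = np.zeros(S.shape[0])
    n = len(rxn_ids)
    ranges: dict[str, tuple[float, float]] = {}
    index = {rid: j for j, rid in enumerate(rxn_ids)}
    for rid in reaction_ids:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo_status, x, lo = backend.solve(c, S, b_eq, bounds)
        c[j] = -1.0
        hi_status, x, hi = backend.solve(c, S, b_eq, bounds)
        if lo_status != "optimal" or hi_status != "optimal":
            raise RuntimeError(
                f"FVA subproblem for {rid}: {lo_status}/{hi_status}"
            )
        ranges[rid] = (lo, -hi)
    return FVAResult(ranges=ranges, fraction=fraction, objective_value=opt)
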