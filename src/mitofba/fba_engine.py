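"""Steady-state flux balance analysis.

Solves max/min c.v subject to S.v = 0 and lb <= v <= ub with the HiGHS LP
solver (scipy.optimize.linprog).  Columns are fed to the solver in a fixed
ordering (category, then id) so that vertex selection is reproducible.

Besides plain optimisation this module provides:

* :func:`reference_fluxes` -- the parsimonious optimum (among all optima of
  the objective, the flux vector minimising total absolute internal flux).
  Printed flux values of a single-solve FBA study are vertex-dependent; the
  parsimonious solution is a reproducible stand-in for "flux under normal
  conditions" and is the denominator of all knockdown fractions.
* :func:`flux_variability` -- per-reaction min/max flux at a fixed objective
  fraction, quantifying alternate optima.
* :func:`blocked_reactions` -- the capable/blocked partition (a reaction is
  capable iff it can carry |flux| > 1e-6 somewhere in the feasible region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import (
    CAT_BOUNDARY,
    CAT_OBJECTIVE,
    FLUX_EPS,
    Model,
    ObjectiveSpec,
    StoichiometricMatrix,
    build_matrix,
)

#: LP feasibility/optimality tolerance.
LP_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}

_HIGHS_OPTS = {
    "presolve": True,
    "primal_feasibility_tolerance": LP_TOL,
    "dual_feasibility_tolerance": LP_TOL,
}


@dataclass
class FluxState:
    """One LP solution: flux per reaction, objective value, solver status."""

    flux: Dict[str, float]
    objective_id: str
    objective_value: float
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    minimum: float
    maximum: float

    def __contains__(self, value: float) -> bool:
        return self.minimum - 1e-6 <= value <= self.maximum + 1e-6


class _LP:
    """Cached LP arrays for one model."""

    def __init__(self, model: Model):
        self.model = model
        self.sm: StoichiometricMatrix = build_matrix(model)
        rxns = [model.reactions[rid] for rid in self.sm.reaction_ids]
        self.lb = np.array([r.lb for r in rxns], dtype=float)
        self.ub = np.array([r.ub for r in rxns], dtype=float)
        self.n = len(rxns)
        self.internal_mask = np.array(
            [r.category not in (CAT_BOUNDARY, CAT_OBJECTIVE) for r in rxns], dtype=bool
        )

    def col(self, reaction_id: str) -> int:
        try:
            return self.sm.rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"reaction {reaction_id!r} not in model") from None

    def solve(
        self,
        c: np.ndarray,
        maximise: bool,
        extra_ub: Optional[Tuple[sparse.spmatrix, np.ndarray]] = None,
        extra_eq: Optional[Tuple[sparse.spmatrix, np.ndarray]] = None,
    ):
        sign = -1.0 if maximise else 1.0
        A_eq: sparse.spmatrix = self.sm.matrix
        b_eq = np.zeros(A_eq.shape[0])
        if extra_eq is not None:
            A_eq = sparse.vstack([A_eq, extra_eq[0]], format="csr")
            b_eq = np.concatenate([b_eq, extra_eq[1]])
        kwargs = {}
        if extra_ub is not None:
            kwargs["A_ub"] = extra_ub[0]
            kwargs["b_ub"] = extra_ub[1]
        res = linprog(
            sign * c,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
            options=_HIGHS_OPTS,
            **kwargs,
        )
        return res

    def state_from(self, res, objective_id: str, maximise: bool) -> FluxState:
        status = _STATUS.get(res.status, "numerical")
        if status != "optimal":
            return FluxState({}, objective_id, float("nan"), status)
        v = res.x
        flux = {rid: float(v[j]) for rid, j in self.sm.rxn_index.items()}
        obj = float(v[self.col(objective_id)])
        return FluxState(flux, objective_id, obj, "optimal")


def _objective_id(objective: Union[str, ObjectiveSpec]) -> str:
    return objective.id if isinstance(objective, ObjectiveSpec) else objective


def _objective_sense(model: Model, objective: Union[str, ObjectiveSpec]) -> bool:
    """True for maximise."""
    if isinstance(objective, ObjectiveSpec):
        return objective.sense == "maximise"
    spec = model.objectives.get(objective)
    return spec.sense == "maximise" if spec else True


def steady_state_residual(model: Model, state: FluxState) -> float:
    """max |S.v| over non-boundary metabolites (0 for an exact solution)."""
    sm = build_matrix(model)
    v = np.array([state.flux[rid] for rid in sm.reaction_ids])
    return float(np.max(np.abs(sm.matrix @ v))) if sm.shape[0] else 0.0


def optimize(model: Model, objective: Union[str, ObjectiveSpec]) -> FluxState:
    """Maximise (or minimise) the objective pseudo-reaction's flux.

    Infeasible or unbounded problems are reported in ``status``, never as
    silent zeros.
    """
    obj_id = _objective_id(objective)
    lp = _LP(model)
    c = np.zeros(lp.n)
    c[lp.col(obj_id)] = 1.0
    res = lp.solve(c, maximise=_objective_sense(model, objective))
    return lp.state_from(res, obj_id, True)


def reference_fluxes(model: Model, objective: Union[str, ObjectiveSpec]) -> FluxState:
    """Parsimonious optimum: minimise total |internal flux| at fixed optimum.

    Two-stage LP.  Stage 1 finds the optimal objective value; stage 2, with
    the objective pinned, minimises the sum of absolute fluxes over internal
    (non-boundary, non-pseudo) reactions via the standard variable split
    t_i >= |v_i|.
    """
    obj_id = _objective_id(objective)
    maximise = _objective_sense(model, objective)
    lp = _LP(model)
    j_obj = lp.col(obj_id)
    c1 = np.zeros(lp.n)
    c1[j_obj] = 1.0
    res1 = lp.solve(c1, maximise=maximise)
    if res1.status != 0:
        return lp.state_from(res1, obj_id, maximise)
    opt = float(res1.x[j_obj])

    internal = np.flatnonzero(lp.internal_mask)
    m = len(internal)
    n = lp.n
    # variables x = [v (n), t (m)]
    S = lp.sm.matrix
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], m))], format="csr")
    pin = sparse.csr_matrix(([1.0], ([0], [j_obj])), shape=(1, n + m))
    A_eq = sparse.vstack([A_eq, pin], format="csr")
    b_eq = np.concatenate([np.zeros(S.shape[0]), [opt]])
    # v_i - t_i <= 0 ; -v_i - t_i <= 0
    rows, cols, data = [], [], []
    for k, j in enumerate(internal):
        rows += [k, k, m + k, m + k]
        cols += [j, n + k, j, n + k]
        data += [1.0, -1.0, -1.0, -1.0]
    A_ub = sparse.csr_matrix((data, (rows, cols)), shape=(2 * m, n + m))
    b_ub = np.zeros(2 * m)
    c2 = np.concatenate([np.zeros(n), np.ones(m)])
    bounds = np.vstack(
        [np.column_stack([lp.lb, lp.ub]), np.column_stack([np.zeros(m), np.full(m, 2e3)])]
    )
    res2 = linprog(
        c2,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTS,
    )
    if res2.status != 0:
        # pinning at the exact optimum can fail numerically; fall back to the
        # vertex solution rather than report a spurious infeasibility
        return lp.state_from(res1, obj_id, maximise)
    v = res2.x[:n]
    flux = {rid: float(v[j]) for rid, j in lp.sm.rxn_index.items()}
    return FluxState(flux, obj_id, opt, "optimal")


def flux_variability(
    model: Model,
    objective: Union[str, ObjectiveSpec],
    fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
) -> List[FluxRange]:
    """Per-reaction flux range subject to objective >= fraction * optimum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    obj_id = _objective_id(objective)
    maximise = _objective_sense(model, objective)
    lp = _LP(model)
    j_obj = lp.col(obj_id)
    c = np.zeros(lp.n)
    c[j_obj] = 1.0
    res = lp.solve(c, maximise=maximise)
    if res.status != 0:
        raise RuntimeError(f"base optimisation failed: {_STATUS.get(res.status)}")
    opt = float(res.x[j_obj])
    # objective >= fraction*opt  (maximise)  /  <= for minimise
    sign = -1.0 if maximise else 1.0
    row = sparse.csr_matrix(([sign], ([0], [j_obj])), shape=(1, lp.n))
    rhs = np.array([sign * fraction * opt])
    targets = list(reactions) if reactions is not None else list(lp.sm.reaction_ids)
    out: List[FluxRange] = []
    for rid in targets:
        cj = np.zeros(lp.n)
        cj[lp.col(rid)] = 1.0
        lo = lp.solve(cj, maximise=False, extra_ub=(row, rhs))
        hi = lp.solve(cj, maximise=True, extra_ub=(row, rhs))
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA solve failed for {rid}")
        out.append(
            FluxRange(rid, float(lo.x[lp.col(rid)]), float(hi.x[lp.col(rid)]))
        )
    return out


def blocked_reactions(
    model: Model, reactions: Optional[Iterable[str]] = None, tol: float = FLUX_EPS
) -> Dict[str, List[str]]:
    """Partition reactions into flux-capable and blocked.

    A reaction is capable iff max |flux| > ``tol`` over the feasible region
    (at most two LPs per reaction).  The partition is exhaustive and is
    invariant under reaction reordering.
    """
    lp = _LP(model)
    targets = sorted(reactions) if reactions is not None else list(lp.sm.reaction_ids)
    capable: List[str] = []
    blocked: List[str] = []
    for rid in targets:
        j = lp.col(rid)
        c = np.zeros(lp.n)
        c[j] = 1.0
        hi = lp.solve(c, maximise=True)
        if hi.status == 0 and hi.x[j] > tol:
            capable.append(rid)
            continue
        if lp.lb[j] < 0:
            lo = lp.solve(c, maximise=False)
            if lo.status == 0 and lo.x[j] < -tol:
                capable.append(rid)
                continue
        blocked.append(rid)
    return {"capable": capable, "blocked": blocked}
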