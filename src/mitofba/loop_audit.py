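"""Detection of thermodynamically infeasible internal flux loops.

A type II/III extreme pathway is an internal circulation that carries flux
with no net exchange across the system boundary.  Such loops are
thermodynamically disallowed and are eliminated from curated models by
directionality constraints.

Two audits are provided:

* :func:`find_internal_loops` follows the classical procedure: constrain all
  boundary exchanges to zero flux and solve under each objective -- any
  remaining nonzero internal flux can only be a loop.  (Objective drains
  other than the one being probed are also zeroed, since an open pseudo
  drain would act as a boundary.)  After the objective solve, total internal
  flux is maximised at the fixed objective value so that circulation, which
  a parsimonious vertex would hide, is actually exhibited.
* :func:`probe_loop_capacity` is strictly stronger: with every boundary and
  pseudo drain closed it maximises each internal reaction individually, so
  it finds loops that are invisible to every objective.

Audits never mutate the input model, and they report rather than auto-fix:
directionality repairs are supplied by the user as constraint tables,
mirroring literature-driven curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .model_core import (
    CAT_BOUNDARY,
    CAT_OBJECTIVE,
    FLUX_EPS,
    Model,
    ObjectiveSpec,
)
from .fba_engine import _LP, _STATUS, blocked_reactions

#: Loop flux threshold: same value as the global flux-zero threshold.
LOOP_TOL = FLUX_EPS


@dataclass
class LoopReport:
    """Per-probe lists of (reaction-id, flux) with |flux| above threshold."""

    entries: Dict[str, List[Tuple[str, float]]] = field(default_factory=dict)
    structural_errors: List[str] = field(default_factory=list)

    @property
    def loop_free(self) -> bool:
        return not self.structural_errors and all(not v for v in self.entries.values())

    def loop_reactions(self) -> List[str]:
        seen = set()
        for hits in self.entries.values():
            seen.update(rid for rid, _ in hits)
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (probe, rid, flux)
            for probe, hits in sorted(self.entries.items())
            for rid, flux in hits
        ]
        return pd.DataFrame(rows, columns=["probe", "reaction_id", "flux"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        if self.loop_free:
            return "loop-free: no internal flux with all boundaries closed"
        lines = [f"{len(self.loop_reactions())} loop-capable reaction(s):"]
        for probe, hits in sorted(self.entries.items()):
            for rid, flux in hits:
                lines.append(f"  [{probe}] {rid}: {flux:.6g}")
        lines += [f"  STRUCTURAL: {e}" for e in self.structural_errors]
        return "\n".join(lines)


def _zero_boundaries(model: Model, keep_open: Optional[str] = None) -> Model:
    """Copy of the model with boundary exchanges and pseudo drains closed."""
    out = model.copy()
    for r in out.reactions.values():
        if r.category in (CAT_BOUNDARY, CAT_OBJECTIVE) and r.id != keep_open:
            r.lb = 0.0
            r.ub = 0.0
    return out


def find_internal_loops(
    model: Model, objectives: Optional[Iterable[Union[str, ObjectiveSpec]]] = None
) -> LoopReport:
    """Objective-driven loop audit under zeroed boundary conditions.

    For each objective: solve with every boundary exchange (and every other
    pseudo drain) constrained to zero, then maximise the summed internal flux
    at the fixed objective value.  All internal reactions with
    |flux| > threshold are reported; in a loop-free model every list is
    empty.  The input model is restored unchanged (audits work on a copy).
    """
    if objectives is None:
        objectives = sorted(model.objectives)
    report = LoopReport()
    for r in model.ordered_reactions():
        if r.category in (CAT_BOUNDARY, CAT_OBJECTIVE) and (r.lb > 0 or r.ub < 0):
            report.structural_errors.append(
                f"boundary/pseudo reaction {r.id} has a forced-nonzero bound "
                f"[{r.lb}, {r.ub}]: the zero-boundary audit is ill-posed"
            )
    for obj in objectives:
        obj_id = obj.id if isinstance(obj, ObjectiveSpec) else obj
        zeroed = _zero_boundaries(model, keep_open=obj_id)
        lp = _LP(zeroed)
        c = np.zeros(lp.n)
        c[lp.col(obj_id)] = 1.0
        res = lp.solve(c, maximise=True)
        if res.status != 0:
            report.structural_errors.append(
                f"objective {obj_id}: {_STATUS.get(res.status)} under zero "
                "boundaries -- a forced-nonzero bound exists"
            )
            report.entries[obj_id] = []
            continue
        obj_val = float(res.x[lp.col(obj_id)])
        if obj_val > LOOP_TOL:
            report.structural_errors.append(
                f"objective {obj_id} reaches {obj_val:.3g} with all boundaries "
                "closed: mass created from nothing"
            )
        # exhibit circulation: maximise total internal flux at fixed objective
        pin = sparse.csr_matrix(
            ([1.0], ([0], [lp.col(obj_id)])), shape=(1, lp.n)
        )
        c2 = np.where(lp.internal_mask, 1.0, 0.0)
        res2 = lp.solve(
            c2, maximise=True, extra_eq=(pin, np.array([obj_val]))
        )
        v = res2.x if res2.status == 0 else res.x
        hits = [
            (rid, float(v[j]))
            for rid, j in sorted(lp.sm.rxn_index.items())
            if lp.internal_mask[j] and abs(v[j]) > LOOP_TOL
        ]
        report.entries[obj_id] = hits
    return report


def probe_loop_capacity(model: Model) -> LoopReport:
    """Per-reaction loop probe: supersets :func:`find_internal_loops`.

    With all boundaries and pseudo drains closed, each internal reaction is
    maximised (and, if reversible, minimised).  A model passing this probe
    carries no internal circulation under any objective.
    """
    zeroed = _zero_boundaries(model)
    lp = _LP(zeroed)
    hits: List[Tuple[str, float]] = []
    for rid in sorted(lp.sm.rxn_index):
        j = lp.col(rid)
        if not lp.internal_mask[j]:
            continue
        c = np.zeros(lp.n)
        c[j] = 1.0
        hi = lp.solve(c, maximise=True)
        if hi.status == 0 and hi.x[j] > LOOP_TOL:
            hits.append((rid, float(hi.x[j])))
            continue
        if lp.lb[j] < 0:
            lo = lp.solve(c, maximise=False)
            if lo.status == 0 and lo.x[j] < -LOOP_TOL:
                hits.append((rid, float(lo.x[j])))
    return LoopReport(entries={"probe": hits})


def verify_flux_capability(model: Model) -> Dict[str, List[str]]:
    """Re-verify that every reaction can still carry flux.

    Run after directionality edits: a direction constraint added to break a
    loop must not leave a reaction permanently blocked.  Delegates to
    :func:`mitofba.fba_engine.blocked_reactions`.
    """
    return blocked_reactions(model)
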