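"""Disease simulation: knockdown scans, threshold searches, relief scans.

An enzyme deficiency is modelled by clamping the corresponding reaction to a
fraction of its flux in the normal-condition reference optimum (the
parsimonious solution of :func:`mitofba.fba_engine.reference_fluxes`), since
residual enzyme activity and reaction flux are not directly correlated.
The clamp preserves the direction of the reference flux: bounds become
``[min(0, f*ref), max(0, f*ref)]``.

Presets are shipped for three TCA-cycle disorders -- fumarase deficiency
(R01082MM, which additionally needs a fumarate efflux path added to the
model), succinate dehydrogenase deficiency (R02164MM) and 2-oxoglutarate
dehydrogenase deficiency (R01700MM; the E3-subunit variant also constrains
the shared dihydrolipoamide dehydrogenase step R07618MM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .model_core import (
    CAT_BOUNDARY,
    FLUX_EPS,
    INF,
    Model,
    strip_compartment_suffix,
    add_efflux_path,
)
from .fba_engine import FluxState, reference_fluxes
from .fixtures import MINIMITO_PATHWAYS


@dataclass
class DiseasePreset:
    """An enzyme deficiency: reactions to constrain plus model edits."""

    name: str
    reaction_ids: List[str]
    efflux_paths: List[str] = field(default_factory=list)
    default_fractions: List[float] = field(
        default_factory=lambda: [1.0, 0.33, 0.0]
    )

    def prepare(self, model: Model) -> Model:
        """Apply the preset's model edits (efflux paths), not the clamp."""
        out = model
        for met in self.efflux_paths:
            out = add_efflux_path(out, met)
        return out

    def clamp(
        self, model: Model, fraction: float, reference: FluxState
    ) -> Model:
        """Clamp each preset reaction to ``fraction`` of its reference flux."""
        out = model.copy()
        for rid in self.reaction_ids:
            ref = reference.flux[rid]
            lo, hi = min(0.0, fraction * ref), max(0.0, fraction * ref)
            r = out.reactions[rid]
            r.lb, r.ub = lo, hi
        return out


#: The shipped disorder presets.  The 33%/0% default fractions follow the
#: convention of probing a residual-activity level and a complete loss.
PRESETS: Dict[str, DiseasePreset] = {
    "fumarase": DiseasePreset(
        "fumarase", ["R01082MM"], efflux_paths=["FumMM"]
    ),
    "succinate_dehydrogenase": DiseasePreset(
        "succinate_dehydrogenase", ["R02164MM"]
    ),
    "alpha_ketoglutarate_dehydrogenase": DiseasePreset(
        "alpha_ketoglutarate_dehydrogenase", ["R01700MM"]
    ),
    "e3_deficiency": DiseasePreset(
        "e3_deficiency", ["R01700MM", "R07618MM"]
    ),
}

#: Named reaction sets used by :func:`pathway_activity` (fixture-model ids).
PATHWAYS = MINIMITO_PATHWAYS


@dataclass
class ScanPoint:
    value: Union[float, str]  # knockdown fraction or relieved boundary id
    objective_value: float
    status: str
    effluxes: Dict[str, float] = field(default_factory=dict)
    pathways_active: Dict[str, bool] = field(default_factory=dict)


@dataclass
class ScanResult:
    swept: str  # "fraction" or "boundary"
    objective_id: str
    points: List[ScanPoint] = field(default_factory=list)

    def objective_series(self) -> Dict[Union[float, str], float]:
        return {p.value: p.objective_value for p in self.points}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            rows.append(
                {
                    self.swept: p.value,
                    "objective_value": p.objective_value,
                    "status": p.status,
                    "effluxes": ";".join(
                        f"{k}={v:.6g}" for k, v in p.effluxes.items()
                    ),
                    "pathways_active": ";".join(
                        k for k, on in p.pathways_active.items() if on
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def efflux_profile(state: FluxState, model: Model) -> Dict[str, float]:
    """Boundary exchanges carrying efflux-direction flux above threshold.

    Efflux direction means the exchange consumes an internal species (the
    ``XCyto -> X_b`` convention); the profile is sorted by descending flux.
    """
    if not state.optimal:
        raise ValueError("efflux_profile requires a solved (optimal) state")
    out: Dict[str, float] = {}
    for r in model.reactions.values():
        if r.category != CAT_BOUNDARY:
            continue
        internal = [
            (mid, c)
            for mid, c in r.stoichiometry.items()
            if mid in model.metabolites and not model.metabolites[mid].is_boundary
        ]
        if len(internal) != 1:
            continue
        _, coef = internal[0]
        v = state.flux.get(r.id, 0.0)
        # consumed internal species with positive flux, or produced with
        # negative flux (a reversible uptake running backwards)
        efflux = v if coef < 0 else -v
        if efflux > FLUX_EPS:
            out[r.id] = efflux
    return dict(sorted(out.items(), key=lambda kv: -kv[1]))


def pathway_activity(
    state: FluxState,
    pathway: Union[str, Iterable[str]],
    pathways: Optional[Dict[str, List[str]]] = None,
    tol: float = FLUX_EPS,
) -> bool:
    """True iff any member reaction carries |flux| above threshold."""
    if isinstance(pathway, str):
        table = pathways if pathways is not None else PATHWAYS
        if pathway not in table:
            raise KeyError(f"unknown pathway {pathway!r}")
        members = table[pathway]
    else:
        members = list(pathway)
    missing = [rid for rid in members if rid not in state.flux]
    if missing and not state.flux:
        raise ValueError("state carries no fluxes")
    return any(abs(state.flux.get(rid, 0.0)) > tol for rid in members)


def _solved_point(
    model: Model,
    objective: str,
    value: Union[float, str],
    pathways: Optional[Dict[str, List[str]]],
) -> ScanPoint:
    state = reference_fluxes(model, objective)
    if not state.optimal:
        return ScanPoint(value, float("nan"), state.status)
    active = {}
    if pathways:
        for name, members in pathways.items():
            present = [rid for rid in members if rid in model.reactions]
            if present:
                active[name] = pathway_activity(state, present)
    return ScanPoint(
        value, state.objective_value, "optimal",
        effluxes=efflux_profile(state, model), pathways_active=active,
    )


def knockdown_scan(
    model: Model,
    reaction_id: str,
    fractions: Sequence[float],
    objective: str,
    pathways: Optional[Dict[str, List[str]]] = None,
    reference: Optional[FluxState] = None,
) -> ScanResult:
    """Clamp ``reaction_id`` to each fraction of its reference flux, re-solve.

    Infeasible points are recorded with their status and the scan continues.
    The input model is never mutated.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"reaction {reaction_id!r} not in model")
    ref = reference or reference_fluxes(model, objective)
    if not ref.optimal:
        raise RuntimeError(f"reference solve failed: {ref.status}")
    rv = ref.flux[reaction_id]
    result = ScanResult(swept="fraction", objective_id=objective)
    for f in fractions:
        clamped = model.copy()
        r = clamped.reactions[reaction_id]
        r.lb, r.ub = min(0.0, f * rv), max(0.0, f * rv)
        result.points.append(_solved_point(clamped, objective, f, pathways))
    return result


# -- event predicates for threshold_search ----------------------------------

def efflux_onset(metabolite_or_boundary: str) -> Callable[[FluxState, Model], bool]:
    """Event: the metabolite is effluxed from the system (flux > threshold)."""

    base = strip_compartment_suffix(metabolite_or_boundary)

    def _event(state: FluxState, model: Model) -> bool:
        profile = efflux_profile(state, model)
        for rid in profile:
            internal = [
                mid
                for mid in model.reactions[rid].stoichiometry
                if mid in model.metabolites
                and not model.metabolites[mid].is_boundary
            ]
            if internal and strip_compartment_suffix(internal[0]) == base:
                return True
        return False

    return _event


def pathway_inactive(
    pathway: Union[str, Iterable[str]],
    pathways: Optional[Dict[str, List[str]]] = None,
) -> Callable[[FluxState, Model], bool]:
    """Event: no member of the pathway carries flux."""

    def _event(state: FluxState, model: Model) -> bool:
        return not pathway_activity(state, pathway, pathways)

    return _event


def threshold_search(
    model: Model,
    reaction_id: str,
    event: Callable[[FluxState, Model], bool],
    objective: str,
    grid: float = 0.01,
    refine: float = 0.001,
    reference: Optional[FluxState] = None,
) -> Optional[float]:
    """Largest knockdown fraction at which ``event`` holds.

    The event must be monotone in the fraction (holding for every fraction
    below its onset); this is checked empirically over the coarse grid.  The
    grid is walked at 1% steps and the bracketing interval bisected to 0.1%.
    Returns ``None`` if the event holds nowhere in [0, 1].
    """
    ref = reference or reference_fluxes(model, objective)
    if not ref.optimal:
        raise RuntimeError(f"reference solve failed: {ref.status}")
    rv = ref.flux[reaction_id]

    cache: Dict[float, Optional[bool]] = {}

    def holds(f: float) -> Optional[bool]:
        key = round(f, 9)
        if key not in cache:
            clamped = model.copy()
            r = clamped.reactions[reaction_id]
            r.lb, r.ub = min(0.0, f * rv), max(0.0, f * rv)
            state = reference_fluxes(clamped, objective)
            cache[key] = event(state, clamped) if state.optimal else None
        return cache[key]

    steps = int(round(1.0 / grid))
    fracs = [i * grid for i in range(steps, -1, -1)]  # 1.0 down to 0.0
    onset = None
    for f in fracs:
        h = holds(f)
        if h:
            onset = f
            break
    if onset is None:
        return None
    # monotonicity spot-check below the onset
    below = [f for f in fracs if f < onset]
    for f in below[:: max(1, len(below) // 5)]:
        if holds(f) is False:
            raise RuntimeError(
                f"event is not monotone over the scan grid (fails at {f:.2f} "
                f"below onset {onset:.2f})"
            )
    if onset >= 1.0:
        return 1.0
    lo, hi = onset, onset + grid  # holds at lo, not at hi
    while hi - lo > refine:
        mid = (lo + hi) / 2.0
        if holds(mid):
            lo = mid
        else:
            hi = mid
    return round(lo / refine) * refine


def uptake_relief_scan(
    model: Model,
    preset: Union[str, DiseasePreset],
    fraction: float,
    boundaries: Sequence[str],
    objective: str,
    release_to: Optional[float] = None,
    pathways: Optional[Dict[str, List[str]]] = None,
) -> ScanResult:
    """Release constrained boundary uptakes one at a time under a disease.

    The preset is applied at the given residual fraction; then, for each
    boundary exchange in turn, its upper bound is raised to ``release_to``
    (default: the unconstrained sentinel) and the objective re-optimised.
    All other boundaries keep their normal constraints; the model is
    restored between trials.  The first scan point, labelled ``"baseline"``,
    is the un-relieved disease state.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    prepared = preset.prepare(model)
    ref = reference_fluxes(prepared, objective)
    if not ref.optimal:
        raise RuntimeError(f"reference solve failed: {ref.status}")
    diseased = preset.clamp(prepared, fraction, ref)
    result = ScanResult(swept="boundary", objective_id=objective)
    result.points.append(_solved_point(diseased, objective, "baseline", pathways))
    target = INF if release_to is None else release_to
    for rid in boundaries:
        if rid not in diseased.reactions:
            raise KeyError(f"boundary reaction {rid!r} not in model")
        trial = diseased.copy()
        trial.reactions[rid].ub = max(trial.reactions[rid].ub, target)
        result.points.append(_solved_point(trial, objective, rid, pathways))
    return result
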