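"""Domain model of a two-compartment mitochondrial metabolic network.

The network follows the conventions of compartmentalised constraint-based
reconstructions of the mitochondrion: metabolites live in the mitochondrial
matrix (id suffix ``MM``), the cytosol (suffix ``Cyto``) or on the system
boundary (suffix ``_b``); reactions carry flux bounds in umol/min/gDW and are
categorised as matrix or cytosolic chemistry, inner-membrane transport steps,
boundary exchanges, or objective pseudo-reactions (drains whose flux is
maximised by the FBA engine).

Stoichiometric coefficients may be exact :class:`fractions.Fraction` values
(e.g. the non-integer proton stoichiometry of ATP synthase); they are only
converted to floating point when the stoichiometric matrix is built.
"""

from __future__ import annotations

import copy as _copy
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: Compartment names.
MATRIX = "matrix"
CYTOSOL = "cytosol"
BOUNDARY = "boundary"
COMPARTMENTS = (MATRIX, CYTOSOL, BOUNDARY)

#: Reaction categories.
CAT_MATRIX = "matrix"
CAT_CYTOSOLIC = "cytosolic"
CAT_TRANSPORT = "transport"
CAT_BOUNDARY = "boundary"
CAT_OBJECTIVE = "objective_pseudo"
CAT_UNKNOWN = "unknown"
CATEGORIES = (CAT_MATRIX, CAT_CYTOSOLIC, CAT_TRANSPORT, CAT_BOUNDARY, CAT_OBJECTIVE)
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES + (CAT_UNKNOWN,))}

#: Infinity sentinel for unconstrained bounds (umol/min/gDW).  LP solvers are
#: better behaved with large finite bounds; no physiological flux in this
#: problem domain approaches this value.
INF = 1000.0

#: Flux below this magnitude is treated as zero everywhere a "no flux" or
#: "efflux observed" judgement is made.
FLUX_EPS = 1e-6

Number = Union[int, float, Fraction]


class StructuralError(ValueError):
    """A model violates a structural invariant (unknown ids, bad bounds...)."""


def compartment_from_id(met_id: str) -> str:
    """Infer the compartment of a metabolite from its id suffix."""
    if met_id.endswith("_b"):
        return BOUNDARY
    if met_id.endswith("MM"):
        return MATRIX
    if met_id.endswith("Cyto"):
        return CYTOSOL
    raise ValueError(f"metabolite id {met_id!r} has no recognised compartment suffix")


def strip_compartment_suffix(met_id: str) -> str:
    """Chemical identity of a metabolite: its id without the compartment tag."""
    for suffix in ("_b", "Cyto", "MM"):
        if met_id.endswith(suffix):
            return met_id[: -len(suffix)]
    return met_id


@dataclass
class Metabolite:
    """A chemical species bound to one compartment.

    ``proton_count`` is the number of protons of the major microspecies at the
    pH of the metabolite's compartment; it is only needed by
    :func:`rebalance_protons`.
    """

    id: str
    name: str = ""
    compartment: str = ""
    proton_count: Optional[int] = None
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.compartment:
            self.compartment = compartment_from_id(self.id)
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not self.name:
            self.name = strip_compartment_suffix(self.id)

    @property
    def is_boundary(self) -> bool:
        return self.compartment == BOUNDARY


@dataclass
class Reaction:
    """Stoichiometry plus flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed, positive = produced).  An irreversible reaction has ``lb == 0``
    (forward-only) or ``ub == 0`` (reverse-only).
    """

    id: str
    stoichiometry: Dict[str, Number]
    lb: float = -INF
    ub: float = INF
    category: str = CAT_UNKNOWN
    direction_note: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def reactants(self) -> Dict[str, Number]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> Dict[str, Number]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lb=self.lb,
            ub=self.ub,
            category=self.category,
            direction_note=self.direction_note,
        )


@dataclass
class ObjectiveSpec:
    """One of the model's objective pseudo-reactions.

    Exactly one objective is active per LP solve; its column in S acts as the
    drain whose flux is maximised (or minimised).
    """

    id: str
    description: str = ""
    sense: str = "maximise"

    def __post_init__(self) -> None:
        if self.sense not in ("maximise", "minimise"):
            raise ValueError(f"objective sense must be maximise/minimise, got {self.sense!r}")


@dataclass
class ConstraintRow:
    reaction_id: str
    lb: float
    ub: float
    source: str = ""


@dataclass
class ConstraintSet:
    """Rows of (reaction-id, lb, ub, source), units umol/min/gDW.

    ``inf``/``-inf`` in a TSV are mapped to the finite sentinel ``±INF``.
    """

    rows: List[ConstraintRow] = field(default_factory=list)

    @staticmethod
    def _parse_bound(value) -> float:
        v = float(value)
        if np.isposinf(v) or v > INF:
            return INF
        if np.isneginf(v) or v < -INF:
            return -INF
        return v

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ConstraintSet":
        df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str, "source": str})
        required = {"reaction_id", "lb", "ub"}
        if not required.issubset(df.columns):
            raise ValueError(f"constraint table must have columns {sorted(required)}")
        rows = [
            ConstraintRow(
                reaction_id=r.reaction_id,
                lb=cls._parse_bound(r.lb),
                ub=cls._parse_bound(r.ub),
                source=getattr(r, "source", "") if pd.notna(getattr(r, "source", "")) else "",
            )
            for r in df.itertuples(index=False)
        ]
        return cls(rows=rows)

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            [(r.reaction_id, r.lb, r.ub, r.source) for r in self.rows],
            columns=["reaction_id", "lb", "ub", "source"],
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class Model:
    """The full network: metabolites, reactions and objective registry."""

    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objectives: Dict[str, ObjectiveSpec] = field(default_factory=dict)
    ph: Dict[str, float] = field(default_factory=lambda: {MATRIX: 8.05, CYTOSOL: 7.3})
    metadata: str = ""

    # -- construction helpers -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for m in rxn.stoichiometry:
            if m not in self.metabolites:
                raise StructuralError(f"reaction {rxn.id} references unknown metabolite {m!r}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    # -- deterministic orderings ----------------------------------------------
    def ordered_reactions(self) -> List[Reaction]:
        """Reactions in the canonical solver ordering: category, then id."""
        return sorted(
            self.reactions.values(), key=lambda r: (_CATEGORY_RANK.get(r.category, 99), r.id)
        )

    def ordered_metabolites(self, include_boundary: bool = False) -> List[Metabolite]:
        mets = [
            m
            for m in self.metabolites.values()
            if include_boundary or not m.is_boundary
        ]
        return sorted(mets, key=lambda m: m.id)

    def reactions_by_category(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for r in self.ordered_reactions():
            out.setdefault(r.category, []).append(r.id)
        return out

    def structurally_equal(self, other: "Model", tol: float = 1e-12) -> bool:
        """Equality of ids, coefficients (to ``tol``), bounds and categories."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for mid, m in self.metabolites.items():
            if m.compartment != other.metabolites[mid].compartment:
                return False
        for rid, r in self.reactions.items():
            o = other.reactions[rid]
            if r.category != o.category:
                return False
            if abs(r.lb - o.lb) > tol or abs(r.ub - o.ub) > tol:
                return False
            if set(r.stoichiometry) != set(o.stoichiometry):
                return False
            for m, c in r.stoichiometry.items():
                if abs(float(c) - float(o.stoichiometry[m])) > tol:
                    return False
        if set(self.objectives) != set(other.objectives):
            return False
        return True


@dataclass
class StoichiometricMatrix:
    """Sparse S: rows are non-boundary metabolites, columns are reactions.

    Boundary (``_b``) species contribute no steady-state row, which keeps
    S.v = 0 well-posed while boundary exchanges remain ordinary columns.
    """

    matrix: sparse.csr_matrix
    metabolite_ids: List[str]
    reaction_ids: List[str]
    met_index: Dict[str, int]
    rxn_index: Dict[str, int]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.matrix.shape

    def to_stoichiometries(self) -> Dict[str, Dict[str, float]]:
        """Round-trip back to per-reaction stoichiometries (non-boundary part)."""
        coo = self.matrix.tocoo()
        out: Dict[str, Dict[str, float]] = {rid: {} for rid in self.reaction_ids}
        for i, j, v in zip(coo.row, coo.col, coo.data):
            out[self.reaction_ids[j]][self.metabolite_ids[i]] = v
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_matrix(model: Model) -> StoichiometricMatrix:
    """Build the stoichiometric matrix S from a validated model.

    Deterministic: the same model always yields identical index maps (rows
    sorted by metabolite id; columns by category then reaction id).
    """
    mets = model.ordered_metabolites(include_boundary=False)
    rxns = model.ordered_reactions()
    met_index = {m.id: i for i, m in enumerate(mets)}
    rxn_index = {r.id: j for j, r in enumerate(rxns)}
    rows, cols, data = [], [], []
    for r in rxns:
        for mid, coef in r.stoichiometry.items():
            if mid not in model.metabolites:
                raise StructuralError(
                    f"reaction {r.id} references unknown metabolite {mid!r}"
                )
            i = met_index.get(mid)
            if i is None:  # boundary species: no steady-state row
                continue
            rows.append(i)
            cols.append(rxn_index[r.id])
            data.append(float(coef))
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(mets), len(rxns)), dtype=float
    )
    return StoichiometricMatrix(
        matrix=mat,
        metabolite_ids=[m.id for m in mets],
        reaction_ids=[r.id for r in rxns],
        met_index=met_index,
        rxn_index=rxn_index,
    )


def find_orphan_metabolites(model: Model) -> List[str]:
    """Non-boundary metabolites participating in at most one reaction.

    An orphan forces zero flux through the single reaction that uses it, so a
    finished model should return an empty list.
    """
    counts: Dict[str, int] = {
        m.id: 0 for m in model.metabolites.values() if not m.is_boundary
    }
    for r in model.reactions.values():
        for mid, coef in r.stoichiometry.items():
            if mid in counts and coef != 0:
                counts[mid] += 1
    return sorted(mid for mid, n in counts.items() if n <= 1)


def apply_constraint_set(model: Model, cs: ConstraintSet) -> Model:
    """Return a copy of ``model`` with bounds replaced as specified.

    Idempotent; unknown reaction ids raise listing every unresolved row.
    """
    missing = [row.reaction_id for row in cs.rows if row.reaction_id not in model.reactions]
    if missing:
        raise StructuralError(f"constraint rows reference unknown reactions: {missing}")
    out = model.copy()
    for row in cs.rows:
        r = out.reactions[row.reaction_id]
        r.lb = max(row.lb, -INF)
        r.ub = min(row.ub, INF)
        if row.source:
            r.direction_note = row.source
    return out


_PROTON_BASE = "H"


def _is_proton(met_id: str) -> bool:
    return strip_compartment_suffix(met_id) == _PROTON_BASE


def rebalance_protons(
    reaction: Reaction, proton_table: Mapping[str, int]
) -> Reaction:
    """Adjust the free-proton coefficient so proton totals balance.

    ``proton_table`` maps every non-proton metabolite id in the reaction to
    the proton count of its major microspecies at the compartment pH.  The
    returned reaction has equal total protons on both sides; all non-proton
    coefficients are unchanged.
    """
    non_proton = [m for m in reaction.stoichiometry if not _is_proton(m)]
    missing = [m for m in non_proton if m not in proton_table]
    if missing:
        raise ValueError(
            f"reaction {reaction.id}: no proton_count for species {missing}"
        )
    compartments = {compartment_from_id(m) for m in non_proton}
    compartments.discard(BOUNDARY)
    proton_species = [m for m in reaction.stoichiometry if _is_proton(m)]
    if len(compartments) > 1 and not proton_species:
        raise ValueError(
            f"reaction {reaction.id} spans compartments {sorted(compartments)} "
            "with no per-compartment free-proton species to absorb the imbalance"
        )
    # signed proton total contributed by the non-proton species
    imbalance = Fraction(0)
    for m in non_proton:
        coef = reaction.stoichiometry[m]
        imbalance += Fraction(coef) * proton_table[m]
    out = reaction.copy()
    if proton_species:
        target = proton_species[0]
        keep = sum(Fraction(out.stoichiometry[m]) for m in proton_species[1:])
        out.stoichiometry[target] = -(imbalance + keep)
    else:
        comp = compartments.pop() if compartments else MATRIX
        suffix = {MATRIX: "MM", CYTOSOL: "Cyto"}[comp]
        if imbalance != 0:
            out.stoichiometry[f"{_PROTON_BASE}{suffix}"] = -imbalance
    # drop a zero proton coefficient for tidiness
    for m in list(out.stoichiometry):
        if _is_proton(m) and out.stoichiometry[m] == 0:
            del out.stoichiometry[m]
    return out


def proton_imbalance(reaction: Reaction, proton_table: Mapping[str, int]) -> Fraction:
    """Signed total proton production of a reaction (0 = balanced)."""
    total = Fraction(0)
    for m, coef in reaction.stoichiometry.items():
        count = 1 if _is_proton(m) else proton_table[m]
        total += Fraction(coef) * count
    return total


def add_efflux_path(model: Model, matrix_metabolite_id: str) -> Model:
    """Add a matrix->cytosol transport step and a cytosol->boundary exchange.

    Used for disease simulation where a metabolite that accumulates in vivo
    (e.g. fumarate in fumarase deficiency) has no efflux route in the default
    model.  Both added reactions are efflux-only (lb = 0).  Calling twice is
    an idempotent no-op with a logged warning.
    """
    met = model.metabolites.get(matrix_metabolite_id)
    if met is None or met.compartment != MATRIX:
        raise StructuralError(
            f"{matrix_metabolite_id!r} is not a matrix metabolite of this model"
        )
    base = strip_compartment_suffix(matrix_metabolite_id)
    t_id, ex_id = f"T_{base}_efflux", f"EX_{base}_out"
    if t_id in model.reactions or ex_id in model.reactions:
        logger.warning("efflux path for %s already present; no-op", base)
        return model.copy()
    out = model.copy()
    cyto_id, b_id = f"{base}Cyto", f"{base}_b"
    if cyto_id not in out.metabolites:
        out.add_metabolite(Metabolite(id=cyto_id))
    if b_id not in out.metabolites:
        out.add_metabolite(Metabolite(id=b_id))
    out.add_reaction(
        Reaction(
            id=t_id,
            stoichiometry={matrix_metabolite_id: -1, cyto_id: 1},
            lb=0.0,
            ub=INF,
            category=CAT_TRANSPORT,
            direction_note=f"disease-modelling efflux step for {base}",
        )
    )
    out.add_reaction(
        Reaction(
            id=ex_id,
            stoichiometry={cyto_id: -1, b_id: 1},
            lb=0.0,
            ub=INF,
            category=CAT_BOUNDARY,
            direction_note=f"disease-modelling efflux boundary for {base}",
        )
    )
    return out


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{k}: {v}" for k, v in sorted(self.counts.items())]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def transport_conserves_species(rxn: Reaction) -> bool:
    """True iff consumed and produced chemical identities are equal multisets."""
    consumed: Dict[str, Fraction] = {}
    produced: Dict[str, Fraction] = {}
    for mid, coef in rxn.stoichiometry.items():
        base = strip_compartment_suffix(mid)
        side = consumed if coef < 0 else produced
        side[base] = side.get(base, Fraction(0)) + abs(Fraction(coef))
    return consumed == produced


def validate_model(model: Model) -> ValidationReport:
    """Structural validation: ids, suffixes, bounds, categories, orphans."""
    rep = ValidationReport()
    for m in model.metabolites.values():
        try:
            inferred = compartment_from_id(m.id)
            if inferred != m.compartment:
                rep.errors.append(
                    f"metabolite {m.id}: suffix implies {inferred}, has {m.compartment}"
                )
        except ValueError:
            rep.warnings.append(f"metabolite {m.id}: no recognised compartment suffix")
    for r in model.reactions.values():
        if r.lb > r.ub:
            rep.errors.append(f"reaction {r.id}: lb > ub")
        for mid in r.stoichiometry:
            if mid not in model.metabolites:
                rep.errors.append(f"reaction {r.id}: unknown metabolite {mid}")
        if r.category == CAT_TRANSPORT and not transport_conserves_species(r):
            rep.errors.append(
                f"transport reaction {r.id} does not conserve chemical species"
            )
        if r.category == CAT_BOUNDARY:
            non_b = [
                m
                for m in r.stoichiometry
                if m in model.metabolites and not model.metabolites[m].is_boundary
            ]
            if len(non_b) != 1:
                rep.errors.append(
                    f"boundary reaction {r.id} must touch exactly one internal species"
                )
        if r.category == CAT_OBJECTIVE and r.id not in model.objectives:
            rep.errors.append(f"objective pseudo-reaction {r.id} not registered")
        if r.category == CAT_UNKNOWN:
            rep.warnings.append(f"reaction {r.id}: unknown category")
    orphans = find_orphan_metabolites(model)
    for o in orphans:
        rep.errors.append(f"orphan metabolite {o}")
    if not model.reactions:
        rep.errors.append("no reactions")
    by_cat = model.reactions_by_category()
    rep.counts["metabolites"] = len(model.metabolites)
    rep.counts["metabolites_internal"] = sum(
        1 for m in model.metabolites.values() if not m.is_boundary
    )
    rep.counts["reactions_total"] = len(model.reactions)
    for cat, ids in by_cat.items():
        rep.counts[f"reactions_{cat}"] = len(ids)
    # the inventory convention of the source reconstruction: "reactions"
    # counts matrix + cytosolic chemistry only
    rep.counts["reactions_chemistry"] = rep.counts.get("reactions_matrix", 0) + rep.counts.get(
        "reactions_cytosolic", 0
    )
    return rep
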