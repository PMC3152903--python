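"""SBML reading and writing.

Models are written as SBML Level 2 Version 4 with flux bounds carried as
``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters and objective
pseudo-reactions marked by ``OBJECTIVE_COEFFICIENT`` -- the convention of
2011-era constraint-based reconstructions.  The reader additionally accepts
Level 3 files with the FBC package (bounds as referenced parameters, the
objective from the FBC objective list), normalising either dialect to
``Reaction.lb``/``Reaction.ub``.

Compartment conventions follow the two-compartment mitochondrial layout:
metabolite id suffix ``MM`` = mitochondrial matrix, ``Cyto`` = cytosol and
``_b`` = system boundary (boundary species carry the SBML
``boundaryCondition`` flag and contribute no steady-state row).

Reaction categories are stored in the reaction notes on write; on read they
are recovered from the notes when present and otherwise inferred from id
suffixes and stoichiometry shape (a reaction whose consumed and produced
chemical species are equal multisets differing only in compartment is a
transport step).  Unknown ids are accepted verbatim; there is no online
lookup.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Union

import libsbml

from .model_core import (
    BOUNDARY,
    CAT_BOUNDARY,
    CAT_CYTOSOLIC,
    CAT_MATRIX,
    CAT_OBJECTIVE,
    CAT_TRANSPORT,
    CAT_UNKNOWN,
    CYTOSOL,
    INF,
    MATRIX,
    ConstraintSet,
    Metabolite,
    Model,
    ObjectiveSpec,
    Reaction,
    StructuralError,
    compartment_from_id,
    transport_conserves_species,
    validate_model,
)
from .fba_engine import FluxState

_COMPARTMENT_SID = {MATRIX: "mito_matrix", CYTOSOL: "cytosol", BOUNDARY: "boundary"}
_SID_COMPARTMENT = {v: k for k, v in _COMPARTMENT_SID.items()}


def _clamp(v: float) -> float:
    return max(-INF, min(INF, v))


def infer_category(rxn: Reaction, model: Model) -> str:
    """Classify a reaction from its stoichiometry shape and id suffixes."""
    comps = set()
    any_boundary = False
    for mid in rxn.stoichiometry:
        met = model.metabolites.get(mid)
        comp = met.compartment if met else None
        if comp is None:
            try:
                comp = compartment_from_id(mid)
            except ValueError:
                return CAT_UNKNOWN
        if comp == BOUNDARY:
            any_boundary = True
        else:
            comps.add(comp)
    if any_boundary:
        return CAT_BOUNDARY
    if len(comps) > 1 and transport_conserves_species(rxn):
        return CAT_TRANSPORT
    if MATRIX in comps:
        return CAT_MATRIX
    if comps == {CYTOSOL}:
        return CAT_CYTOSOLIC
    return CAT_UNKNOWN


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _notes(text: str) -> str:
    return (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>{text}</p></body></notes>"
    )


def write_sbml(model: Model, path: Union[str, Path]) -> None:
    """Serialise a validated model to SBML L2V4.

    Ids and bounds are preserved to 17 significant digits, so a round trip
    reproduces rational coefficients such as 8/3 within 1e-12.
    """
    rep = validate_model(model)
    if not rep.ok:
        raise StructuralError("model fails validation:\n" + "\n".join(rep.errors))
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel("mitofba_model")
    meta_lines = [f"metadata: {model.metadata}" if model.metadata else "metadata:"]
    meta_lines.append(
        "ph: " + ",".join(f"{k}={v}" for k, v in sorted(model.ph.items()))
    )
    obj_descr = ";".join(
        f"{o.id}:{o.sense}:{o.description}" for o in sorted(model.objectives.values(), key=lambda o: o.id)
    )
    meta_lines.append(f"objectives: {obj_descr}")
    sm.setNotes(_notes(" | ".join(meta_lines)))

    for comp_name, sid in _COMPARTMENT_SID.items():
        c = sm.createCompartment()
        c.setId(sid)
        c.setConstant(True)
        c.setSize(1.0)

    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        s = sm.createSpecies()
        s.setId(met.id)
        s.setName(met.name)
        s.setCompartment(_COMPARTMENT_SID[met.compartment])
        s.setInitialConcentration(0.0)
        s.setBoundaryCondition(met.is_boundary)
        extras = []
        if met.proton_count is not None:
            extras.append(f"proton_count: {met.proton_count}")
        if met.formula:
            extras.append(f"formula: {met.formula}")
        if extras:
            s.setNotes(_notes(" | ".join(extras)))

    for rxn in model.ordered_reactions():
        r = sm.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.lb < 0)
        note = f"category: {rxn.category}"
        if rxn.direction_note:
            note += f" | note: {rxn.direction_note}"
        r.setNotes(_notes(note))
        for mid, coef in rxn.stoichiometry.items():
            c = float(coef)
            if c < 0:
                sr = r.createReactant()
                sr.setSpecies(mid)
                sr.setStoichiometry(-c)
            elif c > 0:
                sr = r.createProduct()
                sr.setSpecies(mid)
                sr.setStoichiometry(c)
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseFormula("FLUX_VALUE"))
        for pid, val in (
            ("LOWER_BOUND", rxn.lb),
            ("UPPER_BOUND", rxn.ub),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rxn.category == CAT_OBJECTIVE else 0.0),
        ):
            p = kl.createParameter()
            p.setId(pid)
            p.setValue(val)
    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise IOError(f"failed to write SBML to {path}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _strip_notes(obj) -> str:
    if not obj.isSetNotes():
        return ""
    text = libsbml.XMLNode.convertXMLNodeToString(obj.getNotes())
    text = re.sub(r"<[^>]+>", " ", text)
    return re.sub(r"\s+", " ", text).strip()


def _parse_meta(model: Model, notes: str) -> None:
    for part in notes.split(" | "):
        part = part.strip()
        if part.startswith("metadata:"):
            model.metadata = part[len("metadata:"):].strip()
        elif part.startswith("ph:"):
            for pair in part[len("ph:"):].strip().split(","):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    model.ph[k.strip()] = float(v)
        elif part.startswith("objectives:"):
            for entry in part[len("objectives:"):].strip().split(";"):
                if not entry.strip():
                    continue
                bits = entry.split(":", 2)
                oid = bits[0].strip()
                sense = bits[1].strip() if len(bits) > 1 else "maximise"
                descr = bits[2].strip() if len(bits) > 2 else ""
                model.objectives[oid] = ObjectiveSpec(oid, descr, sense)


def _bounds_from_kinetic_law(r) -> Optional[Dict[str, float]]:
    if not r.isSetKineticLaw():
        return None
    kl = r.getKineticLaw()
    out = {}
    for i in range(kl.getNumParameters()):
        p = kl.getParameter(i)
        out[p.getId()] = p.getValue()
    return out or None


def _bounds_from_fbc(doc, r) -> Optional[Dict[str, float]]:
    fbc = r.getPlugin("fbc")
    if fbc is None:
        return None
    sm = doc.getModel()
    out = {}
    for key, getter in (("LOWER_BOUND", "getLowerFluxBound"),
                        ("UPPER_BOUND", "getUpperFluxBound")):
        pid = getattr(fbc, getter)()
        if pid:
            p = sm.getParameter(pid)
            if p is not None:
                out[key] = p.getValue()
    return out or None


def read_sbml(path: Union[str, Path]) -> Model:
    """Parse an SBML file (L2 kinetic-law bounds or L3 FBC) into a Model."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise StructuralError(
            f"malformed SBML at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise StructuralError("SBML file contains no model")
    model = Model()
    _parse_meta(model, _strip_notes(sm))

    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        sid = s.getId()
        comp = _SID_COMPARTMENT.get(s.getCompartment())
        if comp is None:
            try:
                comp = compartment_from_id(sid)
            except ValueError:
                comp = BOUNDARY if s.getBoundaryCondition() else CYTOSOL
        notes = _strip_notes(s)
        proton = None
        formula = None
        mprot = re.search(r"proton_count:\s*(-?\d+)", notes)
        if mprot:
            proton = int(mprot.group(1))
        mform = re.search(r"formula:\s*(\S+)", notes)
        if mform:
            formula = mform.group(1)
        model.add_metabolite(
            Metabolite(id=sid, name=s.getName() or "", compartment=comp,
                       proton_count=proton, formula=formula)
        )

    # FBC objectives, if present
    fbc_model = sm.getPlugin("fbc")
    if fbc_model is not None and hasattr(fbc_model, "getNumObjectives"):
        for i in range(fbc_model.getNumObjectives()):
            obj = fbc_model.getObjective(i)
            for j in range(obj.getNumFluxObjectives()):
                rid = obj.getFluxObjective(j).getReaction()
                sense = "maximise" if obj.getType() == "maximize" else "minimise"
                model.objectives.setdefault(rid, ObjectiveSpec(rid, "", sense))

    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        params = _bounds_from_kinetic_law(r) or _bounds_from_fbc(doc, r) or {}
        lb = _clamp(params.get("LOWER_BOUND", -INF if r.getReversible() else 0.0))
        ub = _clamp(params.get("UPPER_BOUND", INF))
        notes = _strip_notes(r)
        mcat = re.search(r"category:\s*(\w+)", notes)
        direction_note = ""
        mnote = re.search(r"note:\s*(.+)$", notes)
        if mnote:
            direction_note = mnote.group(1).strip()
        rxn = Reaction(id=r.getId(), stoichiometry=stoich, lb=lb, ub=ub,
                       category=CAT_UNKNOWN, direction_note=direction_note)
        if mcat and mcat.group(1) in (
            CAT_MATRIX, CAT_CYTOSOLIC, CAT_TRANSPORT, CAT_BOUNDARY, CAT_OBJECTIVE
        ):
            rxn.category = mcat.group(1)
        else:
            if params.get("OBJECTIVE_COEFFICIENT") or r.getId() in model.objectives:
                rxn.category = CAT_OBJECTIVE
            else:
                rxn.category = infer_category(rxn, model)
        model.add_reaction(rxn)

    # register objective pseudo-reactions found only via notes/coefficients
    for rxn in model.reactions.values():
        if rxn.category == CAT_OBJECTIVE and rxn.id not in model.objectives:
            model.objectives[rxn.id] = ObjectiveSpec(rxn.id, "", "maximise")
    return model


# ---------------------------------------------------------------------------
# Reports and constraint tables
# ---------------------------------------------------------------------------

def write_flux_report(state: FluxState, path: Union[str, Path],
                      model: Model) -> None:
    """TSV of reaction-id, flux (umol/min/gDW), category.

    Rows are ordered by category then id, so reports diff cleanly.
    """
    if not state.optimal:
        raise ValueError(f"cannot report an unsolved state (status={state.status})")
    lines = ["reaction_id\tflux\tcategory"]
    for r in model.ordered_reactions():
        lines.append(f"{r.id}\t{state.flux.get(r.id, 0.0):.10g}\t{r.category}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraint_table(path: Union[str, Path]) -> ConstraintSet:
    return ConstraintSet.from_tsv(path)


def write_constraint_table(cs: ConstraintSet, path: Union[str, Path]) -> None:
    cs.to_tsv(path)
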