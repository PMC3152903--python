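"""Programmatic model generators.

``build_minimito`` constructs "miniMito", a hand-verifiable two-compartment
model of core cardiomyocyte mitochondrial physiology: glycolysis (lumped),
pyruvate import, the full eight-step TCA cycle with an explicit lipoamide
(E3) sub-step shared between pyruvate and 2-oxoglutarate dehydrogenase,
lumped fatty-acid beta-oxidation and ketone-body degradation, an electron
transport chain with explicit proton translocation and a fixed 0.1% electron
leak to superoxide at complex I, ATP synthase with rotor stoichiometry 8/3
H+ per ATP plus one H+ equivalent for adenine-nucleotide/phosphate
transport, the malate-aspartate shuttle, the GABA shunt, anaplerotic probe
uptakes, and six objective pseudo-reactions.  The key boundary bounds mirror
measured cardiomyocyte values (oxygen 19.8, glucose 0.9 umol/min/gDW) so the
maximum-ATP optimum is oxygen-limited.

Only vectorial (translocated) protons are tracked as explicit species
(``HMM``/``HCyto``); scalar chemical protons are assumed buffered.  All
non-integer coefficients are exact rationals.

``build_random_model`` makes seeded random linear-pathway models with
planted orphan metabolites and planted 3-cycles, returning the ground truth
alongside for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

from .model_core import (
    CAT_BOUNDARY,
    CAT_CYTOSOLIC,
    CAT_MATRIX,
    CAT_OBJECTIVE,
    CAT_TRANSPORT,
    INF,
    Metabolite,
    Model,
    ObjectiveSpec,
    Reaction,
)

F = Fraction


@dataclass
class FixtureSpec:
    """Knobs for the generators.  Same seed + knobs => identical model."""

    seed: int = 0
    # random-model knobs
    n_reactions: int = 20
    n_planted_loops: int = 0
    n_planted_orphans: int = 0
    # miniMito feature flags
    ros_branch: bool = True
    gaba_shunt: bool = True
    shuttles: bool = True
    # miniMito study conditions (umol/min/gDW)
    oxygen_uptake: float = 19.8
    glucose_uptake: float = 0.9
    lactate_uptake: float = 0.2
    ketone_uptake: float = 0.27
    fatty_acid_uptake: float = 1.0
    glutamate_uptake: float = 0.05
    probe_uptake: float = 0.01


#: FixtureSpec for the fuel-only configuration whose maximum-ATP optimum has
#: a closed-form hand-computable value (no anaplerotic probe uptakes).
FUEL_ONLY = FixtureSpec(glutamate_uptake=0.0, probe_uptake=0.0)


def _met(model: Model, mid: str) -> None:
    if mid not in model.metabolites:
        model.add_metabolite(Metabolite(id=mid))


def _rxn(model, rid, stoich, lb, ub, category, note=""):
    for mid in stoich:
        _met(model, mid)
    model.add_reaction(
        Reaction(id=rid, stoichiometry=stoich, lb=lb, ub=ub, category=category,
                 direction_note=note)
    )


def build_minimito(spec: Optional[FixtureSpec] = None) -> Model:
    """Build the miniature mitochondrial model.  See module docstring."""
    spec = spec or FixtureSpec()
    m = Model(metadata="miniMito fixture model")

    # ---------------- cytosolic chemistry ----------------
    _rxn(m, "GLYC_Cyto",
         {"GlcCyto": -1, "ADPCyto": -2, "PiCyto": -2, "NADCyto": -2,
          "PyrCyto": 2, "ATPCyto": 2, "NADHCyto": 2, "H2OCyto": 2},
         0, INF, CAT_CYTOSOLIC, "glycolysis, lumped; irreversible")
    _rxn(m, "R00703Cyto",
         {"PyrCyto": -1, "NADHCyto": -1, "LacCyto": 1, "NADCyto": 1},
         -INF, INF, CAT_CYTOSOLIC, "lactate dehydrogenase")
    _rxn(m, "R00258Cyto",
         {"PyrCyto": -1, "GluCyto": -1, "AlaCyto": 1, "AKGCyto": 1},
         -INF, INF, CAT_CYTOSOLIC, "alanine transaminase")
    if spec.shuttles:
        _rxn(m, "R00342Cyto",
             {"MalCyto": -1, "NADCyto": -1, "OAACyto": 1, "NADHCyto": 1},
             -INF, INF, CAT_CYTOSOLIC, "cytosolic malate dehydrogenase (MAS)")
        _rxn(m, "R00355Cyto",
             {"AspCyto": -1, "AKGCyto": -1, "OAACyto": 1, "GluCyto": 1},
             -INF, INF, CAT_CYTOSOLIC, "cytosolic aspartate transaminase (MAS)")

    # ---------------- matrix chemistry: pyruvate node & TCA ----------------
    _rxn(m, "R00209MM",
         {"PyrMM": -1, "CoAMM": -1, "LipMM": -1,
          "AcCoAMM": 1, "CO2MM": 1, "DHLipMM": 1},
         0, INF, CAT_MATRIX, "pyruvate dehydrogenase E1/E2 (lipoamide acceptor)")
    _rxn(m, "R07618MM",
         {"DHLipMM": -1, "NADMM": -1, "LipMM": 1, "NADHMM": 1},
         0, INF, CAT_MATRIX,
         "dihydrolipoamide dehydrogenase (E3, shared with OGDH)")
    _rxn(m, "R00351MM",
         {"AcCoAMM": -1, "OAAMM": -1, "H2OMM": -1, "CitMM": 1, "CoAMM": 1},
         0, INF, CAT_MATRIX, "citrate synthase")
    _rxn(m, "R01325MM", {"CitMM": -1, "IcitMM": 1},
         -INF, INF, CAT_MATRIX, "aconitase")
    _rxn(m, "R00709MM",
         {"IcitMM": -1, "NADMM": -1, "AKGMM": 1, "CO2MM": 1, "NADHMM": 1},
         0, INF, CAT_MATRIX, "isocitrate dehydrogenase (NAD)")
    _rxn(m, "R01700MM",
         {"AKGMM": -1, "CoAMM": -1, "LipMM": -1,
          "SucCoAMM": 1, "CO2MM": 1, "DHLipMM": 1},
         0, INF, CAT_MATRIX, "2-oxoglutarate dehydrogenase E1/E2")
    _rxn(m, "R00405MM",
         {"SucCoAMM": -1, "ADPMM": -1, "PiMM": -1,
          "SucMM": 1, "ATPMM": 1, "CoAMM": 1},
         -INF, INF, CAT_MATRIX, "succinyl-CoA synthetase")
    _rxn(m, "R02164MM",
         {"SucMM": -1, "QMM": -1, "FumMM": 1, "QH2MM": 1},
         0, INF, CAT_MATRIX, "succinate dehydrogenase (complex II)")
    _rxn(m, "R01082MM",
         {"FumMM": -1, "H2OMM": -1, "MalMM": 1},
         -INF, INF, CAT_MATRIX, "fumarase")
    _rxn(m, "R00342MM",
         {"MalMM": -1, "NADMM": -1, "OAAMM": 1, "NADHMM": 1},
         -INF, INF, CAT_MATRIX, "malate dehydrogenase")

    # ---------------- amino-acid node ----------------
    _rxn(m, "R00355MM",
         {"AspMM": -1, "AKGMM": -1, "OAAMM": 1, "GluMM": 1},
         -INF, INF, CAT_MATRIX, "aspartate transaminase (MAS, matrix side)")
    _rxn(m, "R00243MM",
         {"GluMM": -1, "NADMM": -1, "H2OMM": -1,
          "AKGMM": 1, "NH3MM": 1, "NADHMM": 1},
         -INF, INF, CAT_MATRIX, "glutamate dehydrogenase")
    _rxn(m, "R00253MM",
         {"GluMM": -1, "NH3MM": -1, "ATPMM": -1,
          "GlnMM": 1, "ADPMM": 1, "PiMM": 1},
         0, INF, CAT_MATRIX, "glutamine synthetase")

    # ---------------- GABA shunt (2-oxoglutarate -> succinate bypass) -------
    if spec.gaba_shunt:
        _rxn(m, "R00261MM", {"GluMM": -1, "GABAMM": 1, "CO2MM": 1},
             0, INF, CAT_MATRIX, "glutamate decarboxylase")
        _rxn(m, "R01648MM",
             {"GABAMM": -1, "AKGMM": -1, "SSAMM": 1, "GluMM": 1},
             0, INF, CAT_MATRIX, "GABA transaminase")
        _rxn(m, "R00713MM",
             {"SSAMM": -1, "NADMM": -1, "H2OMM": -1, "SucMM": 1, "NADHMM": 1},
             0, INF, CAT_MATRIX, "succinate-semialdehyde dehydrogenase")

    # ---------------- anaplerosis & lumped fuels ----------------
    _rxn(m, "R00344MM",
         {"PyrMM": -1, "HCO3MM": -1, "ATPMM": -1,
          "OAAMM": 1, "ADPMM": 1, "PiMM": 1},
         0, INF, CAT_MATRIX, "pyruvate carboxylase")
    _rxn(m, "FAOX_MM",
         {"PalmMM": -1, "ATPMM": -2, "CoAMM": -8, "NADMM": -7, "QMM": -7,
          "H2OMM": -7,
          "AcCoAMM": 8, "ADPMM": 2, "PiMM": 2, "NADHMM": 7, "QH2MM": 7},
         0, INF, CAT_MATRIX,
         "palmitate beta-oxidation, lumped (incl. 2 ATP-equivalent activation)")
    _rxn(m, "KBDX_MM",
         {"BHBMM": -1, "NADMM": -1, "SucCoAMM": -1, "CoAMM": -1,
          "AcCoAMM": 2, "SucMM": 1, "NADHMM": 1},
         0, INF, CAT_MATRIX,
         "3-hydroxybutyrate degradation, lumped (CoA from succinyl-CoA)")

    # ---------------- electron transport chain ----------------
    # 0.1% of the electrons through complex I leak to superoxide: per NADH
    # (2 e-), 999/1000 of the pairs reduce Q and 2/1000 superoxide are made,
    # each claiming one O2.  Proton pumping is kept at 4 H+ per NADH.
    if spec.ros_branch:
        cplx1 = {"NADHMM": -1, "QMM": -F(999, 1000), "O2MM": -F(1, 500),
                 "HMM": -4,
                 "NADMM": 1, "QH2MM": F(999, 1000), "O2sMM": F(1, 500),
                 "HCyto": 4}
        _rxn(m, "CPLX1_MM", cplx1, 0, INF, CAT_MATRIX,
             "complex I with 0.1% electron leak to superoxide")
        _rxn(m, "R00275MM",
             {"O2sMM": -2, "O2MM": 1, "H2O2MM": 1},
             0, INF, CAT_MATRIX, "superoxide dismutase")
    else:
        _rxn(m, "CPLX1_MM",
             {"NADHMM": -1, "QMM": -1, "HMM": -4, "NADMM": 1, "QH2MM": 1,
              "HCyto": 4},
             0, INF, CAT_MATRIX, "complex I (no ROS branch)")
    # Only vectorial protons are tracked, so the two scalar protons the Q
    # cycle takes from QH2 are booked against the matrix pool: 4 in, 4 out.
    _rxn(m, "CPLX3_MM",
         {"QH2MM": -1, "CytcOxMM": -2, "HMM": -4,
          "QMM": 1, "CytcRedMM": 2, "HCyto": 4},
         0, INF, CAT_MATRIX, "complex III (Q cycle: 4 H+ out per QH2)")
    _rxn(m, "CPLX4_MM",
         {"CytcRedMM": -2, "O2MM": -F(1, 2), "HMM": -2,
          "CytcOxMM": 2, "H2OMM": 1, "HCyto": 2},
         0, INF, CAT_MATRIX, "complex IV (2 H+ out per 2 e-)")
    # Rotor: 8/3 H+ per ATP; +1 H+ equivalent pays for the electrogenic
    # adenine-nucleotide exchange and phosphate symport, so the carriers
    # themselves are H+-free columns.
    _rxn(m, "ATPSYN_MM",
         {"ADPMM": -1, "PiMM": -1, "HCyto": -F(11, 3),
          "ATPMM": 1, "H2OMM": 1, "HMM": F(11, 3)},
         0, INF, CAT_MATRIX,
         "ATP synthase, 8/3 H+/ATP rotor + 1 H+ transport equivalent")
    _rxn(m, "HLEAK_MM", {"HCyto": -1, "HMM": 1},
         0, INF, CAT_MATRIX, "uncoupled proton leak")

    # ---------------- inner-membrane transport ----------------
    _rxn(m, "T_PYR", {"PyrCyto": -1, "PyrMM": 1}, 0, INF, CAT_TRANSPORT,
         "pyruvate carrier")
    _rxn(m, "T_GLU", {"GluCyto": -1, "GluMM": 1}, 0, INF, CAT_TRANSPORT,
         "glutamate carrier")
    if spec.shuttles:
        _rxn(m, "T_AGC", {"GluCyto": -1, "AspMM": -1, "GluMM": 1, "AspCyto": 1},
             0, INF, CAT_TRANSPORT,
             "aspartate-glutamate carrier, MAS direction")
        _rxn(m, "T_OGC", {"MalCyto": -1, "AKGMM": -1, "MalMM": 1, "AKGCyto": 1},
             0, INF, CAT_TRANSPORT,
             "oxoglutarate carrier: malate in / 2-oxoglutarate out")
    _rxn(m, "T_PIC", {"PiCyto": -1, "PiMM": 1}, -INF, INF, CAT_TRANSPORT,
         "phosphate carrier (H+ cost folded into ATP synthase)")
    _rxn(m, "T_ANT", {"ATPMM": -1, "ADPCyto": -1, "ADPMM": 1, "ATPCyto": 1},
         0, INF, CAT_TRANSPORT,
         "adenine nucleotide translocase, export direction")
    _rxn(m, "T_O2", {"O2Cyto": -1, "O2MM": 1}, -INF, INF, CAT_TRANSPORT,
         "oxygen diffusion")
    _rxn(m, "T_CO2", {"CO2MM": -1, "CO2Cyto": 1}, -INF, INF, CAT_TRANSPORT,
         "carbon dioxide diffusion")
    _rxn(m, "T_HCO3", {"HCO3Cyto": -1, "HCO3MM": 1}, 0, INF, CAT_TRANSPORT,
         "bicarbonate entry")
    _rxn(m, "T_H2O", {"H2OCyto": -1, "H2OMM": 1}, -INF, INF, CAT_TRANSPORT,
         "water")
    _rxn(m, "T_H2O2", {"H2O2MM": -1, "H2O2Cyto": 1}, 0, INF, CAT_TRANSPORT,
         "hydrogen peroxide release")
    _rxn(m, "T_PALM", {"PalmCyto": -1, "PalmMM": 1}, 0, INF, CAT_TRANSPORT,
         "carnitine shuttle, lumped")
    _rxn(m, "T_BHB", {"BHBCyto": -1, "BHBMM": 1}, 0, INF, CAT_TRANSPORT,
         "ketone body entry")
    _rxn(m, "T_GLN", {"GlnMM": -1, "GlnCyto": 1}, 0, INF, CAT_TRANSPORT,
         "glutamine export")
    _rxn(m, "T_NH3", {"NH3MM": -1, "NH3Cyto": 1}, 0, INF, CAT_TRANSPORT,
         "ammonia release")
    _rxn(m, "T_SUC", {"SucMM": -1, "SucCyto": 1}, 0, INF, CAT_TRANSPORT,
         "succinate efflux (dicarboxylate carrier, efflux direction)")

    # ---------------- boundary exchanges ----------------
    # Sign convention: uptake is positive flux through an X_b -> XCyto
    # exchange; efflux positive through XCyto -> X_b.  Explicit one-way pairs
    # avoid sign ambiguity.
    def uptake(base: str, ub: float, note: str = "") -> None:
        _rxn(m, f"EX_{base}_in", {f"{base}_b": -1, f"{base}Cyto": 1},
             0, ub, CAT_BOUNDARY, note)

    def efflux(base: str, ub: float = INF, note: str = "") -> None:
        _rxn(m, f"EX_{base}_out", {f"{base}Cyto": -1, f"{base}_b": 1},
             0, ub, CAT_BOUNDARY, note)

    uptake("Glc", spec.glucose_uptake, "measured cardiomyocyte glucose uptake")
    uptake("O2", spec.oxygen_uptake, "measured cardiomyocyte oxygen uptake")
    uptake("Lac", spec.lactate_uptake, "heart takes up lactate")
    efflux("Lac", INF, "lactate overflow marker")
    uptake("Palm", spec.fatty_acid_uptake, "fatty-acid supply, not limiting")
    uptake("BHB", spec.ketone_uptake, "ketone-body supply")
    uptake("Glu", spec.glutamate_uptake, "amino-acid probe uptake")
    uptake("Asp", spec.probe_uptake, "probe uptake (relief-scan target)")
    uptake("Mal", spec.probe_uptake, "probe uptake (relief-scan target)")
    uptake("OAA", spec.probe_uptake, "probe uptake (relief-scan target)")
    uptake("HCO3", spec.probe_uptake, "probe uptake (anaplerotic bypass)")
    efflux("CO2")
    uptake("H2O", INF)
    efflux("H2O")
    efflux("H2O2", INF, "ROS marker")
    efflux("Gln")
    efflux("Ala")
    efflux("AKG", INF, "2-oxoglutarate excretion marker")
    efflux("NH3")
    efflux("Suc", INF, "succinate excretion marker")

    # ---------------- objective pseudo-reactions ----------------
    # Six drains representing the metabolite requirements of the organelle.
    _rxn(m, "OBJ_ATP",
         {"ATPCyto": -1, "H2OCyto": -1, "ADPCyto": 1, "PiCyto": 1},
         0, INF, CAT_OBJECTIVE, "ATP maintenance drain")
    _rxn(m, "OBJ_AA", {"GluMM": -1, "AspMM": -1, "AlaCyto": -1},
         0, INF, CAT_OBJECTIVE, "amino-acid availability drain")
    _rxn(m, "OBJ_RNA",
         {"GlnMM": -1, "ATPMM": -2, "ADPMM": 2, "PiMM": 2},
         0, INF, CAT_OBJECTIVE, "RNA nucleotide drain (N from glutamine)")
    _rxn(m, "OBJ_DNA",
         {"GlnMM": -1, "ATPMM": -3, "ADPMM": 3, "PiMM": 3},
         0, INF, CAT_OBJECTIVE, "DNA nucleotide drain")
    _rxn(m, "OBJ_LIP",
         {"AcCoAMM": -8, "ATPMM": -7, "NADHMM": -14,
          "CoAMM": 8, "ADPMM": 7, "PiMM": 7, "NADMM": 14},
         0, INF, CAT_OBJECTIVE,
         "lipid synthesis drain; membrane ratio PC/PE/PS/CL 40/34/3/18 "
         "normalised to 100%")
    _rxn(m, "OBJ_HAEM", {"SucCoAMM": -8, "CoAMM": 8},
         0, INF, CAT_OBJECTIVE, "haem drain (8 succinyl-CoA per porphyrin)")

    m.objectives = {
        "OBJ_ATP": ObjectiveSpec("OBJ_ATP", "ATP production", "maximise"),
        "OBJ_AA": ObjectiveSpec("OBJ_AA", "amino-acid availability", "maximise"),
        "OBJ_RNA": ObjectiveSpec("OBJ_RNA", "RNA synthesis", "maximise"),
        "OBJ_DNA": ObjectiveSpec("OBJ_DNA", "DNA synthesis", "maximise"),
        "OBJ_LIP": ObjectiveSpec("OBJ_LIP", "lipid synthesis", "maximise"),
        "OBJ_HAEM": ObjectiveSpec("OBJ_HAEM", "haem production", "maximise"),
    }
    return m


# ---------------------------------------------------------------------------
# Named pathway sets for the fixture model
# ---------------------------------------------------------------------------

MINIMITO_PATHWAYS: Dict[str, List[str]] = {
    "tca_cycle": ["R00351MM", "R01325MM", "R00709MM", "R01700MM", "R00405MM",
                  "R02164MM", "R01082MM", "R00342MM"],
    "fatty_acid_oxidation": ["FAOX_MM"],
    "ketone_body_degradation": ["KBDX_MM"],
    "gaba_shunt": ["R00261MM", "R01648MM", "R00713MM"],
    "malate_aspartate_shuttle": ["R00342Cyto", "R00355Cyto", "R00355MM",
                                 "T_AGC", "T_OGC"],
    "electron_transport_chain": ["CPLX1_MM", "CPLX3_MM", "CPLX4_MM",
                                 "R02164MM"],
}


# ---------------------------------------------------------------------------
# Seeded random models with planted defects
# ---------------------------------------------------------------------------

def build_random_model(spec: FixtureSpec) -> Tuple[Model, Dict[str, List[str]]]:
    """Seeded random linear-pathway model with planted orphans and loops.

    Returns ``(model, ground_truth)`` where ground truth lists the planted
    orphan metabolite ids and the planted loop reaction ids.
    """
    if spec.n_reactions < 3:
        raise ValueError("need at least 3 reactions")
    if spec.n_planted_orphans + 3 * spec.n_planted_loops > spec.n_reactions:
        raise ValueError("planted defects exceed the reaction budget")
    rng = random.Random(spec.seed)
    m = Model(metadata=f"random fixture model (seed={spec.seed})")
    truth: Dict[str, List[str]] = {"orphans": [], "loop_reactions": []}

    n_chain = spec.n_reactions - spec.n_planted_orphans - 3 * spec.n_planted_loops
    n_chain = max(n_chain, 1)
    # linear chain X0_b -> X0 -> X1 -> ... -> Xn -> Xn_b through both
    # compartments, with random stoichiometric weights
    species = [f"X{i}MM" if rng.random() < 0.6 else f"X{i}Cyto"
               for i in range(n_chain + 1)]
    for i in range(n_chain):
        a, b = species[i], species[i + 1]
        coef = rng.choice([1, 1, 2])
        if a[:-2 if a.endswith("MM") else -4] == b[:-2 if b.endswith("MM") else -4]:
            cat = CAT_TRANSPORT
        else:
            cat = CAT_MATRIX if b.endswith("MM") else CAT_CYTOSOLIC
        _rxn(m, f"CHAIN{i}", {a: -1, b: coef}, 0, INF, cat)
    first, last = species[0], species[-1]

    def _boundary(met: str, rid: str, direction: str) -> None:
        base = met[:-2] if met.endswith("MM") else met[:-4]
        # boundary exchanges attach to a cytosolic twin of the species
        cyto = f"{base}Cyto"
        if cyto != met:
            _rxn(m, f"T_{base}_rand",
                 {met: -1, cyto: 1} if direction == "out" else {cyto: -1, met: 1},
                 0, INF, CAT_TRANSPORT)
        b = f"{base}_b"
        st = {b: -1, cyto: 1} if direction == "in" else {cyto: -1, b: 1}
        _rxn(m, rid, st, 0, INF, CAT_BOUNDARY)

    _boundary(first, "EX_src_in", "in")
    _boundary(last, "EX_sink_out", "out")

    for k in range(spec.n_planted_orphans):
        host = rng.choice(species[:n_chain])
        oid = f"ORPH{k}MM"
        _rxn(m, f"ORPHSRC{k}", {host: -1, oid: 1}, 0, INF, CAT_MATRIX)
        truth["orphans"].append(oid)

    for k in range(spec.n_planted_loops):
        a, b, c = (f"LOOP{k}_{x}MM" for x in "ABC")
        rids = [f"LOOPR{k}_{x}" for x in "ABC"]
        _rxn(m, rids[0], {a: -1, b: 1}, 0, INF, CAT_MATRIX)
        _rxn(m, rids[1], {b: -1, c: 1}, 0, INF, CAT_MATRIX)
        _rxn(m, rids[2], {c: -1, a: 1}, 0, INF, CAT_MATRIX)
        truth["loop_reactions"].extend(rids)

    # one drain objective on the sink species so every fixture has an LP
    sink_base = last[:-2] if last.endswith("MM") else last[:-4]
    _rxn(m, "OBJ_SINK", {f"{sink_base}Cyto": -1}, 0, INF, CAT_OBJECTIVE)
    m.objectives["OBJ_SINK"] = ObjectiveSpec("OBJ_SINK", "sink drain", "maximise")
    return m, truth
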