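# Methods

## The model class

`mitofba` works with two-compartment constraint-based models of
mitochondrial metabolism.  A model is a set of metabolites bound to the
mitochondrial matrix (`...MM`), the cytosol (`...Cyto`) or the system
boundary (`..._b`), and a set of reactions with flux bounds in
μmol/min/gDW.  Reactions fall into five categories: matrix chemistry,
cytosolic chemistry, inner-membrane transport steps (which change only the
compartment of their species), boundary exchanges (which connect exactly
one internal species to a boundary twin), and objective pseudo-reactions
(drains representing a metabolic demand).  The intermembrane space is not
modelled separately: porins make it continuous with the cytosol, so the
cytosolic compartment stands for everything outside the inner membrane.

Steady-state flux analysis solves

    maximise  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub

where S is the stoichiometric matrix over *non-boundary* metabolites
(boundary species contribute no row, which is what makes the system open)
and c selects one objective pseudo-reaction.  The LP is solved with HiGHS
via `scipy.optimize.linprog`, with primal/dual feasibility tolerances of
1e-9.  Columns are ordered deterministically (category, then id) so vertex
selection is reproducible across runs.

### Sign conventions

Uptake is positive flux through an `X_b → XCyto` exchange and efflux is
positive flux through an `XCyto → X_b` exchange; every exchangeable
metabolite gets explicit one-way columns so that no sign convention has to
be remembered when reading flux tables.  A flux below 1e-6 μmol/min/gDW is
treated as zero wherever a "no flux"/"efflux observed" judgement is made;
this sits four orders of magnitude below any physiologically printed value.
Unconstrained bounds use a finite sentinel of ±1000 μmol/min/gDW, far above
any attainable flux, because LP solvers are better behaved without true
infinities.

### Reference fluxes and alternate optima

A single LP solve returns an arbitrary optimal vertex, so individual
reaction fluxes at an optimum are not unique.  All quantities that depend
on "the flux under normal conditions" — in particular the denominators of
knockdown fractions — therefore use the *parsimonious* optimum: among all
flux vectors achieving the optimal objective value, the one minimising the
total absolute flux through internal (non-boundary, non-pseudo) reactions,
found by a second LP with the standard `t ≥ |v|` variable split.  Flux
variability analysis (per-reaction min/max at a fixed objective fraction)
is reported alongside wherever a single printed flux is compared against.

## Loop auditing

Thermodynamically disallowed internal circulations (type II/III extreme
pathways) carry flux with no boundary exchange.  Two audits are provided.
The classical audit closes every boundary exchange and pseudo drain
(keeping open only the drain being probed, which cannot export mass under
closed boundaries anyway) and solves each objective; because a modern
solver returns a parsimonious-looking vertex, a second stage maximises the
summed internal flux at the fixed objective value so that circulation is
actually exhibited rather than hidden in a degenerate optimum.  The
per-reaction probe is strictly stronger: with everything closed it
maximises (and, for reversible reactions, minimises) each internal reaction
individually.  A circulation that runs one duplicate reaction forwards and
its twin backwards has zero net flux sum and is invisible to the first
audit but not to the probe — precisely the situation created by carrier
proteins encoded as several transport steps over the same metabolites.
Audits report; they never flip directionality themselves.  Repairs are
supplied as constraint tables, because an automatic fix could silently
change the biology.

## The fixture model ("miniMito")

`build_minimito` generates a 72-reaction, 80-metabolite two-compartment
model of core cardiomyocyte mitochondrial physiology: lumped glycolysis,
pyruvate import, the eight-step TCA cycle, lumped palmitate β-oxidation
and 3-hydroxybutyrate degradation, the electron transport chain with
explicit proton translocation, ATP synthase, the malate–aspartate shuttle,
the GABA shunt, a glutamate/glutamine/alanine amino-acid node, pyruvate
carboxylase anaplerosis, and six objective drains (ATP, amino acids, RNA,
DNA, lipids, haem).  The pyruvate and 2-oxoglutarate dehydrogenase
complexes share an explicit lipoamide-regeneration step (dihydrolipoamide
dehydrogenase, the E3 subunit), so constraining that one reaction disables
both complexes — the mechanism behind the E3-deficiency simulation.

### Study conditions (generator defaults)

| boundary | bound (μmol/min/gDW) | rationale |
|---|---|---|
| oxygen uptake | 19.8 | measured uptake of resting heart; makes the ATP optimum oxygen-limited |
| glucose uptake | 0.9 | measured uptake of resting heart |
| lactate uptake | 0.2 | heart is a net lactate consumer; modest supply |
| 3-hydroxybutyrate uptake | 0.27 | ketone bodies a minor fuel at rest |
| palmitate uptake | 1.0 | deliberately generous: fatty-acid supply is not the limiting factor in heart, oxygen is |
| glutamate uptake | 0.05 | small amino-acid anaplerotic supply |
| Asp/Mal/OAA/HCO3 uptakes | 0.01 | probe-level openings, the classical small trial bound; targets of the relief scans |

With these bounds the maximum-ATP solution saturates oxygen and glucose,
derives most acetyl-CoA from fatty acids with glycolysis second and ketone
bodies last, and run the TCA cycle at ≈7 μmol/min/gDW — the qualitative
fingerprint of resting cardiac metabolism.  The bounds were fixed once,
from the physiology above, when the generator was written.

### Electron transport and proton bookkeeping

Only vectorial (translocated) protons are explicit species (`HMM`,
`HCyto`); scalar chemical protons are assumed buffered and do not appear in
reaction stoichiometries.  Under this convention every pump must conserve
tracked protons, so complex III is written 4 H⁺ in / 4 H⁺ out per QH₂ (the
two protons chemically delivered by QH₂ are booked against the matrix
pool), complex I pumps 4 H⁺ per NADH and complex IV 2 H⁺ per electron
pair.  ATP synthase uses the mammalian rotor stoichiometry of 8/3 H⁺ per
ATP (c₈ ring, 3 catalytic sites) plus one H⁺ equivalent for the
electrogenic adenine-nucleotide exchange and phosphate symport, giving
11/3 H⁺ per cytosolic ATP; the carriers themselves are then H⁺-free
columns.  All non-integer coefficients are exact `fractions.Fraction`
values, converted to floats only when the matrix is built.

Complex I leaks 0.1 % of its electrons to superoxide, encoded as fixed
stoichiometric coefficients (999/1000 of electron pairs to QH₂, 2/1000
superoxide per NADH, each superoxide claiming one O₂) so the system stays
a pure LP.  Superoxide dismutates to H₂O₂ (returning half the O₂), and
H₂O₂ leaves through a dedicated efflux, making ROS production directly
readable off the flux vector.

### The pre-registered stoichiometric yield

In the *fuel-only* configuration (`FUEL_ONLY`: probe and glutamate uptakes
zero) the maximum-ATP optimum has a closed form.  Full oxidation of each
fuel yields, per unit taken up:

| fuel | NADH | QH₂ | substrate-level ATP |
|---|---|---|---|
| glucose | 10 | 2 | 4 |
| lactate | 5 | 1 | 1 |
| 3-hydroxybutyrate | 7 | 2 | 1 |
| palmitate | 31 | 15 | 6 |

(Glycolytic NADH reaches the matrix through the malate–aspartate shuttle
at no proton cost; palmitate's count includes the 2 ATP-equivalent
activation; the ketone-body count pays one substrate-level ATP through the
succinyl-CoA transferase step.)  Each NADH pumps 4 + (999/1000)·6 =
4997/500 H⁺ and consumes 1/500 − 1/1000 + 999/2000 = 1001/2000 O₂
(complex-I leak, dismutation credit, complex IV); each QH₂ pumps 6 H⁺ and
consumes ½ O₂; each pumped H⁺ is worth 3/11 ATP.  Because oxygen is the
only shared constraint, the LP is a fractional knapsack: fill fuels in
order of ATP per O₂ (glucose > lactate > ketone > palmitate) until the
oxygen budget of 19.8 is spent.  The test suite and the acceptance script
evaluate this formula in exact rational arithmetic and require the LP
optimum to match it; at the defaults both give 103.509059 μmol/min/gDW.

### What the fixture does and does not emulate

The fixture reproduces the *mechanisms* of the full-scale reconstruction —
oxygen-limited oxidative ATP production, fuel competition, the GABA-shunt
bypass of 2-oxoglutarate dehydrogenase, carrier counter-exchange forcing
2-oxoglutarate efflux when C4 acids are imported, fumarate dead-ending
unless an efflux path is added, lactate overflow when pyruvate is shut out
of the cycle.  It does not reproduce the full model's numbers: with ~70
reactions instead of ~400 its optimum (≈104 μmol/min/gDW) and its disease
thresholds differ from the published full-model values (e.g. its lactate
onset under fumarase knockdown coincides with fatty-acid-oxidation
shutdown at ≈28 % because both are governed by the same cycle-capacity
scarcity, where the full model separates them at 20 % and 28 %).  Passing
fixture tests therefore demonstrates correctness of the machinery and of
the mechanisms, not agreement with any particular full-scale flux value.
Full-model checks run only when the deposited SBML is placed at
`data/iAS253.xml`.

## Disease simulation

Residual enzyme activity does not map linearly onto reaction flux, so
deficiencies are expressed directly as flux clamps: the affected reaction's
bounds become `[min(0, f·ref), max(0, f·ref)]` where `ref` is its
parsimonious reference flux — the clamp preserves the reference direction,
since residual activity of a physiologically one-way enzyme cannot reverse
it.  Scans walk a fraction grid; threshold searches walk a 1 % grid and
bisect the bracketing interval to 0.1 %, verifying empirically that the
event is monotone below its onset.  Relief scans release one boundary at a
time (to the sentinel, or to an explicit trial value such as
5 μmol/min/gDW) with everything else at normal constraints, restoring the
model between trials.

The fumarase preset adds a fumarate efflux path (matrix→cytosol transport
plus exchange, both efflux-only) because the default network has no route
for the metabolite that accumulates in vivo.  The control requirement for
such an addition is that it leaves every objective's optimum unchanged and
that a zero-flux-through-the-path optimal solution exists (FVA minimum 0);
under degenerate optima a particular vertex may legitimately route flux
through the path, so requiring literal zeros in an arbitrary solution
would be the wrong test.

## Numerical choices

* LP feasibility/optimality: 1e-9; flux-zero threshold: 1e-6; loop
  threshold: same 1e-6 (consistency with efflux detection).
* Parsimonious stage-2 LPs pin the objective at its exact stage-1 value;
  if that pin is numerically infeasible the vertex solution is returned
  rather than a spurious failure.
* SBML output is Level 2 Version 4 with kinetic-law bound parameters (the
  dialect of the era this model class comes from); the reader also accepts
  Level 3 FBC bounds.  Coefficients are serialised at 17 significant
  digits, so rationals such as 8/3 round-trip within 1e-12.
* Knockdown curves must be monotone non-decreasing in the residual
  fraction; a violation above 1e-6 fails the suite.

## Known limitations

* Charge balance is not tracked; proton bookkeeping covers only the
  vectorial pool, so membrane-potential effects beyond the fixed H⁺
  stoichiometries are outside the model class.
* The objective-driven loop audit is weaker than the per-reaction probe by
  construction; the probe is the authoritative verdict.
* The lumped fuel reactions (β-oxidation, ketone-body degradation,
  glycolysis) hide their intermediates, so per-step knockdowns inside
  those pathways are not expressible in the fixture.
* Kinetics, metabolite concentrations and accumulation-driven transport
  reversal are out of scope: everything is steady-state LP.
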