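# Methods

## The modeling framework

All analyses operate on a constraint-based metabolic model: a
stoichiometric matrix `S` (metabolites × reactions), flux bounds
`lb ≤ v ≤ ub` in mmol/g-DW/h, and a linear objective `c` (by convention the
biomass pseudo-reaction).  The steady-state assumption `S·v = 0` defines a
flux polytope; FBA selects an optimal vertex, FVA the per-reaction extent
of the optimal (or near-optimal) face.  Reversibility is encoded solely by
`lb < 0`; boundary reactions are normalized at load time to the export
convention (stoichiometric coefficient −1, positive flux = secretion,
negative = uptake), so secretome profiles and media read consistently.

Every linear or mixed-integer program is assembled in one place and solved
with HiGHS (dual simplex for LPs, branch-and-cut for MILPs) through SciPy,
single-threaded with fixed settings, so repeated runs are bit-identical.
Community coupling rows live on the model (`extra_constraints`) and are
appended to every LP/MILP automatically, which is what makes FVA "see"
coupling without special cases.

### Tolerances and numerical choices

* Feasibility: `‖S·v‖∞ ≤ 1e-6`; bound satisfaction to `1e-9`.
* Blocked-reaction threshold: `|v| < 1e-6` over the whole FVA range with no
  objective floor.
* FVA optimality floor: `c·v ≥ γ·Z* − 1e-6·max(1, |Z*|)`.  The relaxation
  prevents floating-point optima from emptying the feasible set; its side
  effect is that fluxes that are exactly determined at the optimum show
  residual spans of order `1e-5`.  Comparative statistics therefore use a
  degenerate-span cutoff of `1e-4` (`fsr_tol`), safely above solver slack
  and far below any real span in the fixtures (≥ 0.1).
* γ defaults to 1.0; it is exposed everywhere because the choice is a
  genuine free parameter of span-based comparisons.
* Minimum-norm solution: the euclidean variant solves the strictly convex
  QP `min ‖v‖² s.t. S·v = 0, bounds, c·v = Z*` with a trust-region
  constrained optimizer started from the FBA vertex (unique optimum;
  thermodynamically spurious cycles collapse toward their norm-minimal
  residual).  A 1-norm LP variant (flux splitting `v = p − q`) is provided
  and used as an automatic fallback if the QP fails to converge.
* iMAT: binaries force `v_i ≥ ε` (forward-active), `v_i ≤ −ε`
  (reverse-active) or `v_i = 0` (silenced); infinite bounds are clamped to
  ±1000 before the MILP and the clamp is recorded in the result.  ε
  defaults to 1.0 flux unit at the API, while the pipeline configuration
  defaults to 0.25 — the largest ε at which the toy host's planted active
  subnetwork (thinnest member: the nucleobase branch at 0.05·Z* ≈ 0.49) is
  simultaneously feasible with margin.  The MILP is solved to a zero MIP
  gap; when multiple optima exist the reported activity is the first
  optimal witness, which on the planted fixtures is provably unique at
  full agreement.

## The comparison statistic

For each reaction shared by a reference condition A and a perturbed
condition B, the flux-span ratio is `FSr = span_A / span_B` with
`span = vmax − vmin`.  Reactions with FSr outside `[low, high]`
(defaults 0.8 and 2) are *affected*: `FSr < low` means the perturbation
widened the reaction's admissible flux range, `FSr > high` that it
narrowed it.  Both thresholds are configurable; the band is deliberately
asymmetric around 1, so anti-symmetry under condition swap holds for the
ratio (`FSr → 1/FSr`) but the "unchanged" band itself is not symmetric —
the property tests encode exactly this.  An alternative `maxabs` mode
ratios `|vmax|` instead of spans for users who prefer comparing maximal
absolute fluxes; span is the primary definition.

Degenerate handling: both spans below tolerance → the record is excluded
from classification; only the denominator below tolerance → FSr = +∞ with
a flag, classified as narrowed.

Secretome comparison classifies shared exchanges by relative difference
`(b − a)/max(|a|, |b|)` at a 5% tolerance (three classes: increased, same,
decreased); the statistic is invariant to uniform flux-unit rescaling.
Enrichment of affected reactions by subsystem uses the exact
hypergeometric upper tail with Benjamini–Hochberg adjustment at 0.05.

## Curation protocol

Expansion with a curated reaction set registers new metabolites first,
rejects id collisions with differing content, skips exact duplicates, and
then checks each new reaction for blockage.  Auto-debugging resolves
blocked reactions in deterministic id-sorted sweeps: every dead-end
product gets a demand `DM_<met>` (bounds 0..1000), every never-produced
reactant a sink `SK_<met>` (−1000..1000), iterated to a fixpoint because
one reaction's sink can be the missing upstream piece of another.  A
`literature_first` mode consumes a user-supplied reaction set before
falling back to the automatic rule.  Every action lands in an append-only
JSON-lines log whose replay on the base model reproduces the curated model
field-by-field — the auditable form of statements like "seven demands and
one sink were added".

## Host–microbe community construction

Each organism is id-prefixed and its extracellular metabolites are bridged
into a shared lumen `[u]` by reversible transports (±1000); organism-level
exchanges on those metabolites are absorbed and replaced by community
exchanges `EX_<met>[u]` whose bounds encode the diet (uptake closed unless
listed).  The host keeps its body-fluid `[b]` exchanges, which is where
the host-only secretome is read.  Optional coupling constraints
`v_j − c·v_bio ≤ u` and `−v_j − c·v_bio ≤ u` (defaults `c = 400`,
`u = 0.01`, microbe side only) prevent flux through a non-growing
organism.  The community objective defaults to host biomass; a joint
(summed) objective is available.  Whether coupling is applied is a
first-class switch because both conventions are in active use.

## What the synthetic fixtures emulate — and what they do not

The toy microbe (26 reactions by default) is a hand-designed template, not
a random graph: a glycolysis-like backbone (2 ATP and 2 pyruvate per
glucose, uptake ≤ 10), a folate branch feeding biomass, acetate (SCFA-like)
and thymidine secretion, amino-acid/nucleobase pools, and parameterizable
secondary branches.  ATP limits growth at `Z* = 10`, so every hand-derived
number in the tests is a small rational.  The toy host adds a body-fluid
compartment, a thymidine→dTMP requirement (the cross-feeding handle), an
ATP-costly folate synthesis, lactate overflow, and a parseable GPR on
every internal reaction.

The reactive-species fixture is a *synthetic stand-in* with the structural
roles of a literature-curated set: 8 reactions over 11 new metabolites
(superoxide dismutation, a Fenton-type hydroxyl source, an NO-synthase
stand-in, peroxynitrite formation, four damage reactions on the
amino-acid/nucleobase pools).  Superoxide is deliberately never produced
(1 sink) and seven damage products never consumed (7 demands), so the
debugging protocol is exercised end-to-end with known bookkeeping.
Species carry charge annotations but no elemental formulas — the reactions
make no claim of mass balance, and a genuinely curated set can be supplied
as TSV instead.

The perturbation pair plants its truth by construction: a demand draining
the folate pool widens the folate-branch spans, and the damage chemistry
(once debugged) widens the amino-acid and nucleobase synthesis spans;
nothing else in the network gains or loses span at any γ.  The negative
control ships the chemistry un-debugged, where every new reaction is
blocked and no span moves.

Passing tests on these fixtures demonstrate that the machinery — span
comparison, MILP extraction, pairing bookkeeping, coupling — is correct on
networks where the answer is provable.  They do not demonstrate biological
realism: the toys have no cofactor balancing beyond ATP, no compartmental
pH/charge effects, no alternative carbon sources, and their flux scale
(uptake normalized to 10) is orders of magnitude above the sub-0.1 biomass
fluxes typical of data-constrained genome-scale models.  Conclusions about
real host–microbe systems require running the same workflows on genuine
reconstructions converted to the TSV dialect.

## Design choices where the design was open

* The affected band is implemented as the complement of `[low, high]`
  with both ends configurable; the inclusive band edges belong to
  "unchanged".
* FSr is span-based primarily; `maxabs` is a secondary mode rather than a
  separate statistic.
* Expression mapping sends high *and* medium evidence to the core-active
  set; NA and unknown genes are skipped inside GPRs (an AND of high and NA
  evaluates high), and reactions with no informative gene stay
  uncategorized.  Literature-derived upregulation lists enter as category
  overrides to high.
* Biomass is always retained in context models regardless of evidence;
  after extraction the healthy-colon biomass is edited (replicating
  nucleobase precursor removed, folate dependency strengthened) while the
  disease model keeps the original biomass, and the model is re-debugged.
* Context-model repair prunes reactions newly blocked by silencing and
  resolves residual dead ends via the standard demand/sink protocol;
  with `repair=False` blocked reactions are reported but retained.
* Workflow problem sizes (26-reaction microbe, 4 secondary branches,
  enumeration oracles on ≤ 8-reaction instances) were chosen so every
  oracle remains exhaustive and the full suite runs in well under a
  minute per module on a single core.

## Known limitations

* Loopless FVA, thermodynamic (ΔG) constraints and dynamic/dFBA analyses
  are out of scope; the euclidean minimum-norm solution suppresses but
  does not forbid spurious cycles.
* SBML support covers core + FBC (species, reactions, bounds, objective,
  gene associations); subsystems and rich annotations survive only in the
  TSV/JSON dialects.
* Communities are limited to one host and one microbe; multi-species and
  abundance-weighted community building are not implemented.
* The GPR grammar is plain and/or/parentheses; complex isozyme dosage
  rules are not modeled.
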