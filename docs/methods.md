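# Methods

## Scope and model

protoforge designs and analyses membrane-insulated enzymatic logic circuits.
A *protosensor model* couples three layers:

1. a reaction network (species with roles metabolite/enzyme/reporter,
   irreversible enzyme-catalysed reactions with optional discrete
   inhibitors),
2. kinetics per reaction — Michaelis–Menten (`mm_uni`) or one of the three
   irreversible two-substrate mechanisms in Cleland's standard forms
   (`ordered_bibi`, `pingpong_bibi`, `random_bibi`), or elementary mass
   action — and
3. a compartment: a well-mixed sphere of diameter d (default 10 μm, volume
   π/6·d³ ≈ 0.52 pL) whose membrane passes selected small molecules with
   permeability P (μm/s) scaled by a dimensionless pore density ρ.
   The Fick flux into the compartment is ρ·P·(6/d)·(c_out − c_in); species
   without a permeability entry, and all enzymes, are retained.

Only irreversible rate forms are used: the circuits of interest are pulled
far from equilibrium by reporter sinks and reverse constants are generally
unavailable for mined parts. Inhibition is discrete (a reaction is silenced
while any of its inhibitors is present); graded inhibition constants are out
of scope.

### Discrete gate semantics

Gate mining asks whether a *reaction subset plus an input/output binding*
computes a truth table under Boolean reachability: starting from the present
species (bound ON inputs plus the subset's pre-loaded internals), species are
added in deterministic simultaneous rounds whenever an active reaction has
all substrates producible, its enzyme producible or pre-loaded, and no
inhibitor currently producible. The "no inhibitor producible" condition of a
least-fixed-point reading is self-referential under negation; the
simultaneous-round closure is the documented deterministic semantics and
agrees with it on inhibitor-free networks. Pre-loaded internals are all
enzymes of the subset plus every substrate that is neither a logical input
nor produced inside the subset — this is exactly the "encapsulated entity"
set used for circuit size accounting (logical inputs arrive from outside and
wire intermediates start at zero, so neither is counted). Symmetric input
slots (e.g. the two inputs of AND) are reported once, in the
lexicographically smallest binding.

Assembly composes mined motifs by species identity: a gate's output species
may feed downstream gate inputs, and several gates producing the same wire
species realize OR. A species touched by two gates that is neither a circuit
input, a wire, nor a declared shared cofactor (the NAD+/NADH couple inside
one circuit is the canonical declaration) rejects the combination. Candidate
circuits are re-verified row-by-row with an independent fixed-point
evaluator and ranked by (enzyme count, entity count, −context score), the
context score counting involved species that share a metabolic-context tag.
The realization search is breadth-bounded (per species and depth, the 40
smallest partial realizations by gate count are kept, OR width ≤ 2,
depth ≤ 3); this preserves the minimal circuits that the ranking returns
first while keeping the search polynomial on dense motif libraries.

### Temporal logic

Specifications use atoms `obs >= c` / `obs <= c` (constants or `$`-prefixed
free threshold variables), `&`, `|`, and F/G with optional time windows,
under piecewise-constant finite-trace semantics clipped to the horizon.
Because every atom constrains one variable by a half-line at each trace
position, the validity domain of a formula is an exact finite union of
axis-aligned closed boxes; conjunction intersects, disjunction and F unite,
G folds intersections across window positions. Boxes are deduplicated,
pruned by containment and coalesced where they differ in a single interval.

The satisfaction degree of an objective point v is sd = 1/(1+vd), where vd
is the minimum over boxes of the Euclidean distance from v to the box with
each coordinate normalized by max(|v_k|, 1e-9). The relative normalization
makes sd unit-invariant across μM- and mM-scale thresholds; sd = 1 iff the
formula is true at v, and an unsatisfiable (empty) domain is scored sd = 0
exactly. The robustness *margin* of a satisfied objective is the normalized
distance from v to the nearest finite box boundary (an unbounded direction
imposes none); margins therefore cap at 1 for OFF-row constraints anchored
at zero output.

### Simulation

ODE integration uses LSODA (default rtol 1e-8, atol 1e-14) on the summed
reaction + transport right-hand side; rates are evaluated on concentrations
clipped at zero and the output trace is clipped, which keeps trajectories
non-negative without event machinery. The exterior reservoir is infinite
(constant boundary concentrations) by default; a finite-well mode couples an
exterior state through the vesicle-to-well volume ratio.

The stochastic path is an exact Gillespie direct method (numba-compiled)
over reaction channels plus two first-order transport channels per permeable
species (influx propensity ρ·P·(6/d)·c_out·N_A·V, efflux the same constant
per molecule — the exact counterpart of the ODE flux). Enzymatic channels
use the mesoscopic Michaelis–Menten propensity a = v(counts/N_A·V)·N_A·V, an
approximation valid when substrate counts greatly exceed enzyme counts;
elementary mechanistic constants for the bi-bi cycles are not available for
mined parts. Trajectories are reproducible per seed. Exact SSA is
event-bounded: at the fixtures' clinical (mM) concentrations a 10-μm
compartment holds ~1e8–1e9 molecules, so stochastic/deterministic agreement
and count-exact conservation are validated on nM-scale systems at the same
geometry, where the law of large numbers is already decisive, with volume
scaling at 10× and 100× confirming convergence; fixture-scale behaviour is
validated deterministically.

### Design analysis and optimization

A design specification attaches to each truth-table row a conjunction:
every ON output must cross its threshold N_on within the signal deadline
(`F[0,T]`), every OFF output must stay at or below R_off through the horizon
(`G[0,H]`); the aggregate score is the minimum row sd. Sensitivity analysis
is one-at-a-time: each concentration parameter is swept over ±1 decade
about nominal (9 log-spaced points) and scored by the range of the aggregate
sd; ties break lexicographically. Landscapes evaluate the per-row and
aggregate sd over two log-spaced parameter axes at a 5-minute evaluation
time by default.

Concentration optimization runs CMA-ES (standard (μ/μ_w, λ) formulation,
λ = 4+⌊3 ln n⌋, σ0 = 0.5 log-decades, samples projected onto the bounds) in
log10 space with default bounds nominal ×/÷ 10³. The fitness is 1 − sd while
the specification is unsatisfied and −margin once satisfied, so any
satisfying vector dominates every unsatisfying one and the optimizer
continues to centre the design; the margin cap of 1 (set by OFF-row
boundaries at zero) gives a natural stopping plateau. Failed simulations
score sd = 0 (logged).

## Fixtures: what is fixed and what is chosen

The three bundled circuits implement a diabetes-complication logic panel.
Stated study conditions: input pairs (glucose+acetone, lactate+ethanol,
glucose+NOx), outputs NADH (340 nm absorbance), resorufin (571–600 nm
fluorescence), ABTS (420 nm), DAF triazole (488–515 nm), encapsulated
entity/enzyme counts 6/4, 5/3, 4/2, clinical ON levels (glucose 1.39 mM,
ketones 17 μM, lactate 10 μM, ethanol 17.4 mM, NOx 1 mM), 10-μm diameter,
60-minute horizon and readout, and a measurable output inside 10 minutes.

Everything else — kcat, Km, Kia, permeabilities, pool sizes, digitization
thresholds, calibration gains — is a repo-curated choice inside
BRENDA-typical ranges, engineered once so the stated structure holds and
documented in each bundle's provenance notes:

* **GluONe** couples glucose oxidation (G1DH: glucose + NAD+ → NADH) to an
  acetone-driven redox cycle (ADH reduces acetone to isopropanol spending
  NADH; AOX re-oxidizes it releasing H2O2; HRP converts H2O2 + Amplex Red to
  resorufin). The acetone branch's maximal rate is kept below G1DH's supply
  so output 1 still reads ON at high ketone levels, and G1DH/ADH are the
  rate-limiting (hence most sensitive) parameters. Km(glucose) = 2 mM places
  the glucose half-max switching concentration near the 1.39 mM clinical
  threshold.
* **LacOH** drives a small NAD+ pool (20 μM) as a redox shuttle between two
  dehydrogenases and a diaphorase reducing ABTS. The diaphorase operates in
  its linear (sub-Km) regime, so the cycle flux scales linearly with the
  carrier pool but sub-linearly with any single enzyme (the partition between
  NAD+ and NADH re-equilibrates around a weakened step); within ±1 decade
  only the NAD+ pool breaks the 10-minute deadline, reproducing its
  dominant sensitivity.
* **GluNOx** charges the same carrier from glucose and discharges it through
  a nitrate/nitrite reductase releasing NO, captured non-enzymatically by
  DAF (mass action, 1e5 /M/s). With the G1DH law shared with GluONe (whose
  Km is pinned by the clinical-switching requirement), the carrier pool
  cannot be separated from the bottleneck enzyme within ±1 decade under the
  deadline-driven score, so this fixture's sensitivity ranking is left
  unpinned; all its parameters are robust at ±1 decade.

Thresholds (N_on, R_off): NADH (200 μM, 20 μM), resorufin (5 μM, 0.5 μM),
ABTS (30 μM, 3 μM), DAF triazole (5 μM, 0.5 μM). Calibration gains are
configuration constants (NADH 6.22e3 AU/M from the 340-nm molar absorptivity
at 1 cm; fluorescence gains arbitrary at 1e6 AU/M).

Multiplexed deployment is modelled two ways: *batch* merges the three
networks into one well (interior pools sum; shared ids such as NAD+/NADH
become one pool — the failure channel), while *encapsulated* co-simulation
keeps each circuit behind its membrane facing the common infinite reservoir,
which decouples the vesicles exactly (no vesicle-to-well volume ratio is
asserted).

## Synthetic data generator

`generate_planted_network` emulates a merged, organism-agnostic metabolic
network at desk scale: metabolites with pathway context tags, enzymes, and
seeded random decoy reactions surrounding gate motifs (BUF, AND, OR with two
parallel producers, ANDN via an annotated inhibitor) planted verbatim;
ground truth is returned for recall and oracle tests. Decoys never produce a
planted output species, which keeps the planted ground truth exact. The
generator does not emulate: shared cofactor stoichiometry across decoys,
reversible reactions, kinetic annotations, or the size distribution of real
BRENDA exports — so mining tests certify algorithmic correctness
(soundness/completeness against brute force), not database-scale motif
counts. `PlantedFeasibleProblem` provides an optimizer ground truth: a
single-gate protosensor whose nominal concentrations satisfy the design
specification by construction.

## Numerical choices

- ODE: LSODA, rtol 1e-8 / atol 1e-14 by default; conservation checks use
  rtol 1e-10 / atol 1e-16. Non-negativity by clipping (see above).
- SSA: event cap 5e7 per trajectory with a directed error advising ODE mode;
  seeds are masked into [0, 2^31).
- Validity domains: closed intervals throughout, so boundary objective
  points count as satisfied, matching the ≥/≤ atom semantics.
- Distance normalization guard ε = 1e-9 protects zero objectives.
- Sensitivity ties and motif/circuit rankings break lexicographically;
  identical inputs yield identical outputs everywhere.
- Truth-table digitization never rounds an intermediate value: levels
  between R_off and N_on are reported as indeterminate, the failure
  signature optimization is meant to eliminate.

## Problem sizes

Default analysis sizes: truth tables up to 3 inputs; mining subsets of
≤ 2 reactions; oracle-equivalence networks of ≤ 12 reactions and recall
networks of 50; SSA validation at 240–300 s horizons with 10–100 seeds
across 1×/10×/100× volumes; CMA-ES budgets of 15 generations for fixture
optimization and 40 for recovery studies. These are the package's own
validation scales; all are parameters.

## Limitations

- Well-mixed interior: no intraparticle diffusion gradients, osmotic
  effects, membrane rupture or vesicle size dispersion.
- Reporters are retained (P = 0) by default; possible leakage of small
  reporter molecules is not modelled.
- Hemolysin pore density enters only as the multiplicative pore_scale on
  permeabilities; it is fixed, not optimized.
- Mesoscopic SSA propensities are an approximation at enzyme-scale counts;
  exact mechanistic decomposition would require elementary constants.
- NOT-logic exists only through annotated inhibitors or explicit
  substrate-competition motifs; pure reachability cannot express negation.
- Two-level composition only (no multi-level logic synthesis beyond the
  OR-by-shared-wire construction); gates with more than 3 inputs are out of
  scope.
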