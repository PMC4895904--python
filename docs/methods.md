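# Methods

## The circuit and its two descriptions

The object of study is a two-gene mutual-repression switch. Each gene's
promoter carries two operator sites for the opposing gene's repressor
oligomer; repressor binding blocks (but does not fully abolish)
transcription, and each protein is diluted by cell growth. Depending on
parameters the circuit has one stable expression state or two
(one per dominant repressor), and in the stochastic dynamics the two
states can exchange by rare fluctuation-driven switches.

### Reduced model

Assuming (i) fixed gene dosage, (ii) DNA-binding and elongation reactions
at steady state, (iii) constant free RNA polymerase, and (iv) fast
dimerization equilibrium, the circuit reduces to two ODEs in the
dimensionless homodimer levels `T1`, `T2` (see README for the equation).
The synthesis term is proportional to `√T` because dimers form from
monomers in instantaneous equilibrium; the decay term collects dimer and
monomer turnover. Time is measured in units of the protein dilution
rate, so reduced-model switching rates are not directly comparable to
wall-clock rates of the full circuit.

Gene-level parameters and defaults (both genes, lambda-CI-based):
`K2 = 20 nM` (repressor–operator), `K1 = 10 nM` (dimerization),
`r = 25` (cooperativity, the product of the per-site factors 2 and 12.5),
`s = 0.01` (leakage), `β = 17.5 /nM` (expression efficiency),
`u = 3.0` (scaled RNAp–promoter dissociation), `σ = 10` (monomer/dimer
lifetime ratio). This point has exactly two stable fixed points and
serves as the bistable reference. The parameter-derivation module
recomputes every chain that is fully documented (dissociation constants
from equilibrium constants, dilution from doubling time, cooperativity,
transcript-length scaling) and flags the one chain that does not
reproduce its adopted value: `u = K3/[R]` with `K3 = 11.2 nM`,
`[R] = 30 nM` gives 0.37, while the adopted table value is 3.0; we keep
the table value and report the mismatch.

**Fixed-point analysis.** Newton refinement from a logarithmic multistart
grid (12×12 starts over `[1e-4, 1e4]²`), deduplication at relative
distance 1e-6, analytic Jacobian, strict `Re λ < 0` for stability; zero
real parts are reported unstable with a `marginal` flag. The origin is a
non-hyperbolic fixed point of the square-root kinetics and is excluded
(states below 1e-6). The 2×2 Newton step is solved component-wise by
Cramer's rule rather than a generic linear solver: every arithmetic
operation then commutes exactly with the gene-swap relabeling, so
symmetric parameter scans are mirror-symmetric to the last bit.

**Birth–death discretization.** The reduced dynamics also run as a
two-species jump process: birth propensity `ω ×` synthesis term at
`T = n/ω`, death propensity `ω ×` decay term, with `ω = 100` molecules
per unit `T` by default (ω is a discretization scale, not a biological
parameter). At the reference point the process occupies two modes
separated by `≈ 2ωT*`, consistent with the deterministic analysis.

### LITR circuit

The full LacI–TetR network has 27 dynamic species (promoter occupancy
states, elongation intermediates, mRNAs, and the monomer/dimer/tetramer
and inducer-bound repressor forms) plus three chemostatted ones: RNA
polymerase (30 nM ≈ 18 molecules at 1 µm³) and the two inducers, whose
extracellular reservoirs fix their copy numbers. Bimolecular rate
constants are in µm³/s and divide by the cell volume (default 1 µm³);
inducer and RNAp concentrations convert at 1 nM ≙ 0.6022 molecules/µm³.
LacI₄ binds the first operator site at `k_l3`, reaches the second site
intramolecularly at `200·k_l3` (the printed constant carries volume
units and is volume-scaled like the bimolecular steps), and singly
IPTG-bound tetramers bind DNA at `0.5·k_l3`; IPTG binding to DNA-bound
tetramers uses `0.5·k_l5` for each of the two possible outcomes.
Inducer-driven displacement from DNA is irreversible. The builder emits
a manifest cross-referencing every reaction to its rate-constant symbol
and lists the reading corrections applied to the printed reaction table
(promoter bookkeeping and lacI/tetR column symmetry force a handful of
rows: the second TetR site binds `TetR2 + d1TetR2`, RNAp on the singly
TetR-bound promoter yields `d1TetR2_R` with a matching initiation row,
and each promoter's initiation feeds its own gene's elongation species).

A deliberate property of this reaction set: DNA-bound repressors do not
degrade or dilute, and LacI₄–DNA dissociation is extremely slow
(`q_l3 = 5.4e-7 /s`, a three-week half-life). Without IPTG, the leak
transcription of lacI therefore guarantees that the tetR promoters are
eventually occupied — the uninduced circuit is deterministically
monostable (LacI wins) at any copy ratio, and bistability with respect
to copy dosage is a stochastic, finite-horizon phenomenon.

## Stochastic engine

Exact direct-method SSA. Per event, all propensities are recomputed
(O(reactions), ~70 for LITR) in a numba-compiled loop; networks with
custom (non-mass-action) propensities use an equivalent Python loop. The
random stream is an explicit PCG32 generator seeded from the run seed;
the state recorded at a sample time is the state after the last event at
or before it (right-continuous). Checkpoints store the counts, event
clock and generator state *before* the first waiting-time draw that
overshoots the horizon, so resuming a run reproduces the unsplit
trajectory bitwise. Tau-leaping is deliberately absent: the
classification below counts exact zero crossings, which approximate
leaping would bias. The engine is validated against closed forms
(exponential decay, Poisson stationarity by chi-square at α = 0.01,
exponential waiting times by Kolmogorov–Smirnov, exact conservation).

## Stability classification

Each condition runs twice for the same span: once from 400 LacI
tetramers, once from 400 TetR dimers (everything else zero, promoters
free). The decision statistic is Δ = active-LacI − active-TetR counts;
by default the active species are the free, inducer-free LacI₄ and
TetR₂ (DNA- and inducer-bound forms excluded; the aggregation is
configurable). After discarding the first 1 % of samples as burn-in:

* **monostable** — strictly more than 95 % of the samples of *both* runs
  lie on one common side of zero;
* **bistable** (strict, "black") — the two Δ histograms share no occupied
  integer bin *and* no zero crossing was observed in either run. The
  no-crossing requirement keeps sparsely occupied histograms from
  producing spurious disjointness;
* **joint bistable** — otherwise; the switching frequency is the mean
  zero-crossing rate of the two runs (zero-valued samples inherit the
  preceding sign).

Per-cell seeds in grid scans derive from the base seed and the cell
index by a splitmix64 hash, recorded in the output sidecars.

## Deterministic network analysis

`dc/dt = Sᵀ v(c)` with classical concentration mass action (homodimer
fluxes go as `c²`; the stochastic drift's `n(n−1)` differs by an exactly
known correction that the tests account for). Steady states: stiff BDF
integration from the two excess-repressor starts plus log-uniform random
multistarts, Newton refinement on the conservation-reduced system
(promoter totals eliminated), stability from the reduced Jacobian's
eigenvalues, deduplication at 1 % relative distance or opposite
`LacI₄ − TetR₂` sign. Grid scans classify each inducer pair
independently; the bistable-region boundary is exported as grid-edge
midpoint segments at the grid's own resolution (no continuation).

## Scaled-down study conditions

The published analysis runs every condition for 1e7 s with 1 s sampling;
desk-scale runs here use the same sampling but shorter spans, chosen
against the phenomenon's timescales rather than as a fixed fraction:

* Single-condition classification default: `t_end = 1e5 s`.
* Inducer-plane heat maps: `t_end = 1e6 s`. The slowest single-copy
  switching is of order 1e-5 Hz (a timescale of days), so a 1e5 s window
  frequently contains no crossing at all and misreads slow joint-bistable
  cells as strictly bistable; a 1e6 s window exceeds that timescale and
  makes the copy-number contrast (no black cells at one copy, a black
  cell inside the deterministic boundary at four copies) reproducible
  across seeds. Both grids fit in a few CPU-minutes.
* Heat-map axes: IPTG ∈ [1e2, 1e5] nM (6 log-spaced values), DOX ∈
  [1, 1e3] nM (4 values) — two decades around the repressor–inducer
  dissociation constants (LacI₄–IPTG ≈ 1e4 nM, TetR₂–DOX ≈ 1.3e2 nM),
  which is where induction actually moves the circuit.
* Reduced-model phase maps: 11×11 (or smaller) grids; the birth–death
  demonstration uses ω = 30 and 50 time units.

Paper-scale spans remain available (`t_end` is ordinary configuration
everywhere). Because strict bistability is defined relative to the
observation span, a "black" cell at 1e6 s asserts a residence time
longer than ~11 days, not absolute stability.

## What the tests do and do not show

The synthetic fixtures (decay, birth–death, dimerization, toy toggle)
have closed-form behavior and validate the engine, not the biology. The
LITR network uses literature point estimates without parameter
uncertainty; cell growth enters only as a first-order dilution, there is
no cell division, no plasmid copy-number fluctuation, no extrinsic
noise, and inducer reservoirs are perfectly chemostatted. Conclusions
about the real LacI–TetR system inherit all of those idealizations.
Desk-scale stochastic maps resolve switching frequencies down to roughly
1/t_end; slower structure requires the paper-scale span. The uninduced
deterministic monostability discussed above means the deterministic and
stochastic copy-ratio results differ qualitatively at zero inducer; the
package reports both rather than reconciling them.
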