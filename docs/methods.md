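# Methods

`crnswitch` decides whether a mass-action chemical reaction network with
moiety conservation can act as a bistable switch, and if so exhibits rate
constants and concentrations that realize the switch. This note records the
model, the numerical choices, and the limits of what the shipped tests
demonstrate.

## Model

A network of N species and R irreversible reactions between complexes
(multisets of species) defines, under mass action, the polynomial ODE
system c' = Y·A·ψ(c), where Y is the species-by-complex molecularity
matrix, A the complex-by-complex rate-constant matrix (zero column sums),
and ψ_j(c) = Π_i c_i^{Y_ij}. Equivalently c' = S·r(c,k) with S the
stoichiometric matrix; the two constructions agree term by term and the
package asserts this symbolically. Reversible input reactions are expanded
into forward/backward pairs with separate rate constants, numbered in
expansion order.

λ = N − rank(S) conservation laws constrain the dynamics to affine slices.
The package requires λ ≥ 1: the bifurcation parameter ("signal") is always
a conserved total, which is the experimentally tunable quantity for
signaling motifs (total kinase, total substrate). Networks without
conservation laws are rejected with an explicit error.

### Conservation laws

A signed rational basis of Null(Sᵀ) is computed exactly (sympy). Because
each law describes a conserved moiety, a nonnegative representative basis
exists; it is recovered by a vertex search of the polytope
{x : B̃x ≥ 0, 1ᵀB̃x = 1} with random objective directions (uniform on
[−1, 1]^λ), solved per direction by linear programming (HiGHS). Vertices
map back through B̃, are rescaled to coprime nonnegative integers (divide
by the smallest nonzero entry, clear denominators, divide by the gcd), and
are collected until λ independent vectors are found. LP solutions are
rationalized (`Fraction.limit_denominator`) and every candidate is verified
exactly against SᵀB = 0 before acceptance, so floating-point vertices can
never corrupt the basis. The default iteration budget is 100·λ; exhaustion
raises an error that advises raising the budget. Columns are presented
sorted by support, which makes the basis independent of the seed whenever
the extreme rays are unique (they are for all three packaged networks).

### Reduction

Only s = rank(S) species ODEs are independent. Given a response species
(the readout, always retained) one species per law is eliminated through
its law; candidate eliminations are scanned in lexicographic species order
and the first combination is taken whose pairing matrix is invertible and
whose retained rows of S still have rank s. Rank decisions are exact
(integer arithmetic); because the per-reaction monomials k_i·ψ are linearly
independent over ℚ, the rank of the retained rows of S equals the symbolic
rank of the retained ODEs, so no numeric sampling is involved. The result
is F(ç, signal, k) with ç ∈ ℝˢ.

### Steady-state parametrization

Mass action makes F linear in any subset of rate constants. Solving
U·k̃ = b for the s constants whose stoichiometric columns are the RREF
pivots of S yields closed forms whose substitution annihilates F
identically (asserted symbolically for every packaged network). If a pivot
set gives a singular U over the rational function field, or forces some
k̃ ≡ 0, the solver falls through the remaining linearly independent column
s-subsets in lexicographic order; exhausting them proves that no steady
state with k > 0, c > 0 exists.

### Saddle search

A saddle-node candidate needs F = 0 and det J = 0, J = ∂F/∂ç. Two
objectives are provided:

* **parametrized** (default): minimize det(J)² over the free rate
  constants and all concentrations, with k̃ reconstructed from its closed
  forms and the conserved totals computed from the sampled concentrations.
  A smooth hinge penalty Σ max(0, −k̃_i + δ)², δ = 1e−12, keeps the
  reconstructed rates positive without hard rejections; evaluation at a
  denominator pole returns a large finite penalty (1e10).
* **explicit residual**: minimize det(J)² + Σ_i F_i², over all rate
  constants and concentrations. Higher-dimensional but robust when the
  parametrized Jacobian is ill-conditioned; the pipeline falls back to it
  automatically when the symbolic solve fails.

The determinant is evaluated numerically (LU) from the lambdified Jacobian;
a symbolic determinant is intractable beyond s ≈ 4.

Each of n starts runs scipy dual annealing (default temperature schedule;
Nelder–Mead local search capped at 600 iterations) followed by a
Nelder–Mead polish, inside user boxes on concentrations and rate constants.
When no boxes are given, physiological defaults apply: concentrations
5e−13…5e−7 M; association 1e4…1e8 M⁻¹s⁻¹ (bimolecular source),
dissociation 1e−5…1e−3 s⁻¹ (unimolecular source, bimolecular target),
catalysis 1e−3…1 s⁻¹ (everything else). The packaged examples use wider
boxes set in their configurations. Per-start seeds are `seed + index`
(mod 2³¹), making runs bit-reproducible and trivially partitionable across
workers.

Search thoroughness is quantified by the multistart stopping rule
q(n, r) = 1 − (n+a+b−1)!(2n+b−r−1)! / ((2n+a+b−1)!(n+b−r−1)!), evaluated
with exact big-integer arithmetic (a = 1, b = 5; r counts local minima
within 10% relative distance of the best). The search stops early when a
start reaches the numerical-zero tolerance (1e−12 on the objective, q set
to 1.0) or when q ≥ 0.95. q is reported as a heuristic; its calibration
for this objective has not been validated.

### Verification of candidates

A candidate is screened as a saddle-node if J has exactly one eigenvalue
with |z| < 1e−6·max(1, ρ(J)) (ρ the spectral radius) and all other
eigenvalues have |Re z| above that threshold; two near-zero eigenvalues
flag a possible codimension-2 point and reject the candidate. The
transversality conditions (signal derivative of F and the second derivative
contracted twice with the kernel vector, both nonzero and outside range(J),
with range membership judged at the same threshold) are advisory only:
failing candidates still go to continuation and simulation, because the
decisive evidence is the diagram itself.

**Continuation.** Pseudo-arclength predictor–corrector on the equilibrium
curve in (ç, ε): tangents from the SVD of the bordered system, Newton
correction orthogonal to the tangent (tolerance 1e−10), step halving on
failure and growth factor 1.3 up to 0.5, initial step 1e−2. Starts at (or
near) a fold are corrected by minimal-norm Gauss–Newton steps that let the
signal move. Folds are detected by sign change of the tangent's signal
component, refined by bisection, and classified as signal-maximal or
signal-minimal; a min/max pair separated by more than 1e−9 relative brackets
the bistable interval. Revisited folds (the two walk directions crossing
the start fold) deduplicate by kind and position.

**Direct simulation.** For each signal value on a grid the reduced ODEs
are integrated (LSODA, rtol 1e−8/atol 1e−10) from a low and a high start
until a steady state. Convergence accepts when the maximum change of the
independent concentrations between successive checkpoints stays below
1e−6 over a trailing window of 3, or when the instantaneous rates fall
below 1e−6 relative to the solution scale — the second clause is needed for
systems crawling along a center manifold, whose windowed differences never
settle. Two start policies exist:

* `response`: perturb only the response species to 0.5× and 2× its
  candidate value, clamped to the interval that keeps every reconstructed
  dependent species nonnegative (5%/95% of that interval when it is
  bounded). Appropriate when the response itself indexes the basins.
* `global`: low start scales the whole independent vector to 2% of the
  candidate; high start is the candidate. Needed when the switching
  variable is not the response — in the prion-type motif the bistability is
  a seeding switch in the kinase-conformation subsystem, and perturbing
  the doubly-phosphorylated readout alone never leaves the seeded basin.

The pipeline tries `response` first and escalates to `global` if no
hysteresis is found. Hysteresis is declared when low- and high-start
equilibria differ by more than 5% of the overall response range on a signal
subinterval; its edges are reported as the up- and down-switching
thresholds. Equilibria whose reconstructed dependent species go negative
are flagged and excluded from the verdict.

## Packaged examples and what the tests show

Three motifs ship with reference decision vectors (6-decimal precision) at
which each network sits at a saddle-node: the Edelstein autocatalytic
network (uniterminal; response [A], signal B_tot), a futile signaling cycle
with a two-state kinase (biterminal; response the phosphorylated substrate,
signal total substrate), and a prion-like double-phosphorylation motif
(biterminal; response the doubly phosphorylated substrate). "Near zero" at
a reference vector is asserted against (1e−3·‖J‖_F)², which accounts for
the 6-decimal rounding amplified by the determinant's gradient.

Computed facts worth recording (all reproduced by the test suite):

* Edelstein: folds of the S-curve at B_tot = 7.778340 and 7.794893; inside
  the window the upper branch spans [A] ≈ 1.49–1.69 and the lower branch
  ≈ 0.98–1.13; switching thresholds from simulation agree with the folds
  within the 0.005 grid.
* Futile cycle: folds at S_tot ≈ 1616.8 and 1672.5; the reference S_tot
  sits at the upper fold.
* Prion motif: the reduced Jacobian at the reference rates is
  near-singular at arbitrary concentrations (smallest singular value
  ~2e−8), which precludes continuation — the documented motivation for the
  explicit-residual mode and direct simulation. The OFF state (no active
  kinase, response ≈ 0) and ON state (response ≈ 120–190) coexist over a
  wide range of total substrate.

The random-network generator used by the property suite builds species
from a fixed pool of conserved moieties and only draws reactions that
recombine them, so every draw has λ ≥ 1 by construction and a known
annihilator of Sᵀ. It emulates closed binding/modification networks; it
does not produce synthesis/degradation fluxes, autocatalysis, or kinetics
other than mass action, so passing properties say nothing about open
systems.

Problem sizes in the default suite — networks up to 9 species/14
reactions, 100 random 5-species networks, 50-start searches, signal grids
of 21–121 points — were chosen so each module is exercised at the scale of
the packaged examples.

## Known limitations

* Only mass-action kinetics; SBML kinetic laws are deliberately ignored
  and stoichiometry is the single source of truth.
* λ = 0 networks and time-dependent signals are out of scope.
* The Bayesian stopping rule assumes the best minimum is at least as
  likely to be found as any other — optimistic for funnel-free landscapes.
* Continuation handles folds only; Hopf or codimension-2 points are
  neither continued nor classified beyond the multiplicity screen.
* The hysteresis verdict is grid-limited: windows narrower than the signal
  grid step can only be found by the continuation route.
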