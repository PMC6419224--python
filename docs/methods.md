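# Methods

## Scope and models

`semiflex` simulates a single self-avoiding semiflexible polymer on a
periodic simple cubic lattice and analyses its stiffness. Three lattice
chain models are implemented:

* **BFM** — the bond fluctuation model. A monomer occupies the eight
  corners of a unit cube; bonds are the 108 integer vectors with squared
  length in {4, 5, 6, 9, 10} (symmetry classes (2,0,0), (2,1,0), (2,1,1),
  (2,2,1), (3,0,0), (3,1,0)). Consecutive bonds realise 87 distinct bond
  angles. The elementary "L6" move shifts one monomer by a unit step along
  one of the six axes.
* **L-BFM** — the Larson-type bond fluctuation model. Single-site monomers
  with bonds of length 1 or sqrt(2) (18 vectors); the elementary move
  displaces a monomer to one of its 18 nearest or next-nearest sites. The
  phrase "bond length 1 or 2" in the coarse-grained literature is read as
  squared length in {1, 2}: only that reading yields 18 move destinations
  and six distinct bond angles.
* **SCLM** — the simple cubic lattice model with unit axial bonds, whose
  only bond angles are 0 and pi/2. With strict unit bonds no axial
  single-monomer move can preserve both adjacent bonds, so under the local
  moves implemented here an SCLM chain is immobile; the model is retained
  for its exactly solvable two-class angle distribution, not for dynamics.

Excluded volume is a hard constraint: no lattice site is occupied twice
(site-disjoint monomer cubes in the BFM). Chain stiffness enters through a
bending energy between successive bonds, either the cosine-angle (CA) form
E/k_BT = k (1 − cos θ) — the discretisation of the worm-like-chain bending
energy — or the cosine-squared-angle (CSA) form E/k_BT = k (1 − cos θ)²,
with θ = 0 for a straight continuation and k in units of k_BT (k_BT = 1).

## Theoretical persistence length

For independent bond angles the Boltzmann average of cos θ has closed
forms: the CA potential gives the Langevin function coth k − 1/k, and the
CSA potential gives 1 − (1 − e^(−4k)) / (sqrt(πk) erf(2 sqrt k)). Both are
validated against adaptive quadrature of the defining integral (relative
tolerance 1e−12; agreement demanded to 1e−8). Below k = 1e−3 the closed
forms lose digits to cancellation and series expansions are used
(k/3 − k³/45 + 2k⁵/945 and 2k/3 − 8k²/45); the branch point is chosen so
both branches agree to ~1e−7 where they meet.

⟨cos θ⟩ is converted to a persistence length either through the
Kuhn-length relation l_p/l = (1 + ⟨cos θ⟩) / (2 (1 − ⟨cos θ⟩)) (default)
or through the orientation-decay form l_p/l = −1 / ln ⟨cos θ⟩. The two
coincide in the stiff regime in which the scaling fits operate; the Kuhn
form is the default because the continuum prediction is derived from it.
In the stiff limit they give l_p/l → k − 1/2 for CA and
l_p/l → sqrt(πk) − 1/2 for CSA; the −1/2 offset is exact and explains why
the bare asymptotes k and sqrt(πk) are approached only to ~3% at k = 100
(CSA) but to well under 1% by k = 10⁴.

On a lattice the bond angle is discrete and the integral becomes a sum
over the model's angle classes weighted by their a-priori probabilities
f_i — the frequency of each angle among all ordered pairs of bond vectors
that a three-monomer chain can realise without violating excluded volume.
Enumeration is exact: pairs are grouped by cos θ with an absolute
tolerance of 1e−9 (cosines are computed from integer dot products, so
values within a class agree to floating-point noise; the grouping is a
sorted merge, not fixed bins). The BFM back-fold filter (overlapping first
and third monomer cubes) is what reduces the raw pair count to the 87
observed classes, with the most probable class at θ = π/2.

The discrete theory produces the qualitatively different stiff-chain
laws: for the BFM with CA the persistence length steepens to an
approximate power law l_p ~ k^2.3 over 40 < k < 100; for the L-BFM the
growth is exponential with rate set by the smallest bending-energy gap —
the 45° angle between a unit and a sqrt(2) bond, giving rates
(1 − 1/sqrt 2) ≈ 0.29 (CA) and (1 − 1/sqrt 2)² ≈ 0.086 (CSA) — and for the
SCLM, with only the gap k between straight and right angle,
l_p → e^k / 4 (the 4 being the multiplicity ratio of right-angle to
straight continuations). Scaling laws are fitted by unweighted least
squares in log space on uniform grids of ≥ 13 points; the default windows
are k ∈ (40, 100) for the BFM power law, k ∈ [30, 80] for the L-BFM CA
rate and k ∈ [100, 280] for the L-BFM CSA rate, chosen so the single-gap
asymptote dominates. Fitted over its default window the CSA rate lands on
the asymptotic 0.086; fitting at lower k, where the next angle class
(cos θ = 1/2) still contributes, yields slightly smaller effective rates,
which is worth remembering when comparing rates quoted from different
windows.

## Monte Carlo algorithm

A Metropolis chain over single-monomer moves: pick a uniform monomer and a
uniform move direction, reject outright if a changed bond leaves the
allowed set or a destination site is occupied, otherwise accept with
probability min{1, e^(−ΔE)} where ΔE sums the (at most three) bending
angles whose bonds the move changes. Proposal probabilities are symmetric
(same monomer, opposite displacement), so Metropolis on ΔE satisfies
detailed balance. For the BFM the bond-vector set itself prevents bond
crossing under L6 moves, so no separate crossing test is needed. One Monte
Carlo step (MCS) is N+1 attempted moves for a chain of N bonds.

The inner loop is a numba-compiled kernel operating on an (N+1, 3) int64
position array (unwrapped) and a dense uint8 occupancy box (wrapped). The
box edge must be a power of two so wrapping is a bitwise AND; the default
is 256, raised to 512 for stiff chains (k > 10) so the chain extent always
stays below half the box edge, which is audited at every sample. Bond
validity and inverse bond lengths are table look-ups indexed by component
offsets. The total bending energy is carried incrementally and compared
against a from-scratch recompute at the end of every run (tolerance 1e−8
relative); correctness of the whole move machinery is additionally pinned
by an exact test: a two-bond chain must sample angle classes with
probability ∝ f_i e^(−E_i), which the simulator reproduces to four decimal
places in ⟨cos θ⟩.

Randomness: the kernel uses numba's NumPy-compatible generator, seeded per
run with (seed + run index); identical configurations reproduce identical
observable series bit for bit. A slow pure-Python `attempt_move` mirrors
the kernel move-for-move and serves as the readable reference and audit
oracle in the tests.

### Initialization and equilibration

Runs start from a straight rod by default. Stiff chains expose a very slow
collective mode in the mean bond-angle cosine: started from a rod the
observable relaxes towards equilibrium from above, started from an
athermal coil (pre-relaxed for 5×10⁵ MCS at k = 0 before the potential is
switched on) it relaxes from below, and at k ≈ 18 the two one-sided
estimates still differ by several percent after 10⁷ MCS. The `mixed`
protocol alternates rod and coil starts between runs, cancelling the
leading initialization bias; it is the protocol for local (bond-angle)
measurements with the CA potential. Two situations demand rod starts
instead, both verified by block-averaged convergence traces: (i) global
size observables of stiff chains — a coil must expand its end-to-end
distance roughly tenfold through the slowest mode of the chain and is
still far from converged after 6×10⁶ MCS, while the rod starts next to
the near-rodlike equilibrium shape; and (ii) any measurement under a
stiff CSA potential — switching a large k(1 − cos θ)² energy onto a coil
leaves the chain kinetically trapped, because every local straightening
path passes through bent intermediates costing of order k. Flexible
chains (k = 0) equilibrate in well under 2×10⁵ MCS, verified by the decay
of Re² from the rod value.

### Problem sizes

Production analyses use chains of N = 50 bonds. Flexible-chain averages
use 10 independent runs of 7×10⁵ MCS after 3×10⁵ MCS equilibration;
stiff-chain averages use 8 runs of 4×10⁶ MCS after 4×10⁶ MCS
equilibration (plus the athermal pre-relaxation on coil-started runs),
sampled every 10⁴ MCS. The scripted experiment profiles scale these down
further (`reduced`: N = 30, 10 runs, ten-fold shorter windows) for smoke
runs.

## Persistence-length estimators

Four estimators operate on the recorded observable series; all report
run-to-run means and standard errors across independent runs (runs are
independent by construction, so no within-run blocking is used).

* `lp_auto`: fit of ln C(s) versus s, C(s) = ⟨b_i · b_{i+s}⟩ / ⟨l⟩². The
  fit window is the contiguous initial decay with C(s) above
  max(0.05, 3 × its run-to-run SE), capped at s = N/4; fewer than three
  usable points raises an error (the correlation of nearly flexible chains
  is ill-defined). The noise floor is a parameter so that noise-free
  series can be fitted exactly.
* `lp_theta = −⟨l⟩ / ln ⟨cos θ⟩`: the local bond-angle measure,
  insensitive to chain length.
* `lp_ee`: Flory's projection ⟨Σ_i b_i · b_1⟩ / ⟨l⟩, ensemble-averaged
  before the division (the alternative order differs only in the third
  decimal); bounded by the contour length.
* `lp_wlc`: inversion of the worm-like-chain ⟨Re²⟩(l_p, L) by bisection on
  (10⁻⁶ L, 10³ L), relative tolerance 1e−10, with L = N⟨l⟩; inputs at or
  beyond the rod limit ⟨Re²⟩ ≥ L² are rejected.

⟨l⟩ is always the time- and run-averaged bond length of the same ensemble,
recomputed per stiffness, because the BFM bond length shifts slightly with
k (athermal value ≈ 2.70, giving a contour length near 135 for N = 50).

## Synthetic ground-truth ensembles

`semiflex.synthetic` builds off-lattice chains with fixed bond length and
independent bond angles drawn exactly from the Boltzmann density
sin θ e^(−E(θ)) — the model underlying the continuous theory. The CA form
is sampled by inverse CDF; the CSA form as a half-Gaussian in 1 − cos θ
truncated at −1 by rejection. These ensembles have no excluded volume, no
lattice discreteness and no dynamic correlations, so estimator tests
against them validate the estimators themselves, not the simulation: on
these chains every estimator must recover −l / ln⟨cos θ⟩ up to sampling
error, and does. Conversely, passing those tests says nothing about
lattice or excluded-volume effects, which is precisely what the lattice
simulations are for.

## What the stiff-chain comparison shows

At the bending constant where the continuous theory predicts l_p/l = 18,
the simulated bond-angle persistence length exceeds the continuum value
for both potentials, much more strongly for CA than for CSA. Two effects
stack: lattice discreteness (captured exactly by the 87-class discrete
average, contributing about +12% for CA and −2% for CSA at this
stiffness) and chain-scale excluded volume, which raises ⟨cos θ⟩ beyond
the two-bond a-priori filter by a comparable amount for both potentials
(roughly +13 to +17 percentage points in l_p). The correctness of the
sampler at the relevant stiffness is pinned exactly by the two-bond
Boltzmann test, and convergence of each production measurement is
established by block-averaged traces and, where feasible, two-sided
initialization; the residual slow-mode uncertainty dominates the
run-to-run standard errors at reduced replication. Literature values for
the CSA deviation that are much smaller than the excluded-volume
contribution measured here most likely reflect initialization bias — a
CSA chain started from a flexible configuration is kinetically arrested
and biases the deviation low.

## Known limitations

* Single dilute chains only: no melts, no multi-chain systems, no
  hydrodynamics, no dynamics analysis beyond what equilibration demands.
* The faster bond-crossing-prone 26-direction move set is deliberately not
  implemented; the BFM uses the traditional L6 move.
* SCLM chains cannot move under the implemented local moves (see above);
  all SCLM results are theory-side.
* The discrete theory ignores excluded volume beyond the two-bond filter,
  so it underestimates the simulated l_p at high stiffness.
* At k ≳ 35 the SCLM/L-BFM discrete ⟨cos θ⟩ is so close to 1 that
  double-precision representation limits the accuracy of −1/ln⟨cos θ⟩;
  scaling fits and limit evaluations stay below that regime.
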