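# Methods

## The model

A protein is a self-avoiding chain of N beads on the simple cubic lattice:
one bead per residue, unit bonds (one lattice spacing = the 3.8 Å
Cα–Cα virtual bond, used only to report gyration radii in ångström), at
most one bead per site.  Two beads form a *contact* when they are
non-bonded lattice nearest neighbours with sequence separation
|i − j| ≥ 3 — the smallest separation geometrically possible on the cubic
lattice, where parity further restricts contacts to odd separations.

Energetics is the native-centric (Gō) contact Hamiltonian

&nbsp;&nbsp;&nbsp;&nbsp;H = Σ_{i<j} ε · Δ(i, j),

with Δ(i, j) = 1 exactly when (i, j) is a contact of the native structure
and ε = −1.  Non-native contacts are sterically allowed but energetically
neutral, so E = −(number of formed native contacts) and the folding
coordinate Q = (formed native contacts)/|native map| satisfies E = −40·Q
for both model systems.  Temperature is measured in units of |ε|/k_B with
k_B = 1.

Dynamics is Metropolis Monte Carlo over the classical local move set:
corner flips (an interior bead with perpendicular bonds hops to the
opposite corner of its square), end moves (a terminal bead relocates to a
uniformly chosen vacant neighbour of its bonded neighbour) and crankshafts
(two interior beads rotate by ±90° or 180° about the axis through their
flanking beads, chosen uniformly among the sterically feasible
rotations).  One MCS (the time unit) is one attempted elementary move;
infeasible attempts count as rejected steps.  An attempt is a crankshaft
with probability p_crank = 0.2 (configurable) and a single-bead move at a
uniformly chosen bead otherwise.  Every move is proposed with the same
probability as its reverse — the candidate sets of forward and reverse
moves have provably equal sizes under this scheme — so detailed balance
holds and the chain samples the Boltzmann distribution of H; the test
suite verifies this against exact enumeration on a 4-bead system.

## Folding setups

* **bulk** — free chain (the in-vitro reference).
* **plane tether** — one terminus is fixed at (0, 0, 1), one lattice
  spacing above a purely steric wall occupying z = 0; every bead must keep
  z ≥ 1, and the anchored bead is never displaced, which removes that
  terminus's end move.
* **point tether** — the anchored bead is fixed in space with no wall (the
  control separating the anchoring constraint from the steric effect of
  the surface).

By the convention of the study reproduced here, bead 1 is the "C-terminus"
(closest to the knotted core) and bead N the "N-terminus".

## The model systems

The study's two targets are published only as printed constraints, not
coordinates, so this package *designs* spec-equivalent structures and
freezes them as fixtures (`src/knotfold/fixtures/protein_{K,U}.txt` with
JSON sidecars recording search seeds and verification reports):

* **protein K** — 41 beads; 40 native contacts; the backbone ties a
  trefoil (|Δ(−1)| = 3) whose minimal knotted segment spans beads 3–22 and
  carries 8 of the 40 contacts; absolute contact order (mean |i − j| over
  contacts) 17.2; compact near-cuboid body with bead 1 extending outside
  it, which makes the chain closure unambiguous.
* **protein U** — 40 beads (one fewer, the extension bead); 40 contacts;
  unknotted; contact order 16.0; and — as the published target — 90% of
  its beads coinciding with protein K sites under the best
  proper-rotation + translation superposition (what the search actually
  achieved is described below).

The K search is staged simulated annealing: an opened window of the
minimal 24-edge lattice trefoil is itself annealed into a 20-bead segment
that is knotted but unknots when either end bead is deleted and carries
exactly 8 internal contacts; tails are grown compactly around this core;
then the whole chain is annealed on a penalty combining contact count,
contact-order sum, core-contact count, compactness and the bead-1
extension, with periodic topology checks that revert any move that breaks
the trefoil or moves the knotted core, reheat cycles, and a final
steepest-descent polish over the exhaustive one-move neighbourhood.  One
further condition the printed constraints imply but do not state is
imposed: both termini must lie on a face of the structure, otherwise the
native state would be geometrically unreachable when that terminus is
tethered one spacing above the wall (the original study folds the chain
tethered by either terminus).  The shipped protein K satisfies every
printed constraint — its knotted core is confirmed both by end deletion
and by brute force over all contiguous windows — with absolute contact
order 17.15, inside the stated ±0.05 of 17.2 (searches for the exact 17.2
sum plateaued two separation units short).

The control was harder.  Deriving a 90%-overlap unknotted chain from a
designed K turned out to be infeasible for every K realization found:
exhaustive enumeration of re-routed backbone windows (all contiguous
windows up to 7 beads, off-site-pruned head re-threads up to 14 beads, and
all complementary two-window combinations) produced no unknotted chain
with 40 contacts and contact order 16 that kept 36 of 40 beads on K sites.
The obstruction is structural: untying requires moving the first beads off
the knotted path, and in every reachable K geometry those beads carry
native contacts that the remaining four-bead freedom cannot re-create
(design variants that forced the first beads contact-free made the K
search itself non-convergent).  The shipped protein U is therefore an
independently designed conforming control — 40 beads, 40 contacts,
contact order exactly 16, unknotted, compact — walked along its
feasibility manifold to the maximum attainable site coincidence with
protein K: 87.5% (35 of 40 beads).  The fixture sidecar records both the
90% target and the achieved value; the acceptance suite asserts the
published figure and that check fails by design rather than being
weakened.  All published quantities that depend on the exact original
geometry beyond the printed constraints carry the same caveat.

## Knot detection

Knottedness of an open chain is defined through a deterministic closure:
each terminus is pushed radially outward from the chain centroid onto a
sphere of radius three times the maximal centroid-to-bead distance, and
the two external points are joined by an arc on that sphere.  All closure
vertices are rounded to integers (the radius makes rounding topologically
harmless) and the polygon is verified to be simple, with deterministic
direction jitters on failure.

The closed polygon is reduced by Koniaris–Muthukumar–Taylor (KMT) vertex
deletion: a vertex is removed when the triangle it forms with its
neighbours intersects no other polygon segment, iterated to a fixed point.
Intersection predicates are exact — int64 arithmetic inside a proven
coordinate bound (numba-compiled hot path) and arbitrary-precision Python
above it; segments sharing a triangle corner block deletion only when they
meet the triangle beyond the shared corner, and ambiguous coplanar
contacts conservatively block deletion, which can only leave the polygon
less reduced, never change its type.

The reduced polygon is classified by the Alexander determinant |Δ(−1)|:
project along deterministically perturbed directions, build the crossing
diagram, assign generator arcs between consecutive underpasses and
evaluate the Alexander matrix at t = −1 (where the entries are independent
of crossing handedness) with an exact integer determinant.  Three
non-degenerate projections must agree.  |Δ(−1)| is 1 for the unknot, 3 for
the trefoil, 5 for the figure-eight; the implementation was validated
against densely sampled parametric curves of five knot types and ships
minimal 24-edge trefoil and 30-edge figure-eight lattice polygons as
canonical fixtures.  The classifier cannot distinguish chirality or some
composite knots — sufficient here, where only unknot/trefoil matter.

The *knotted core* is localized by deleting beads one at a time from
alternating ends, re-closing and re-testing, until deletion from either
end unknots the sub-chain.  On the protein K fixture this equals the
global brute-force smallest knotted window (a property enforced at design
time, so the two notions cannot disagree on the shipped structure).

## Thermodynamics

Equilibrium sampling uses parallel tempering over a geometric temperature
grid (the production default bracketing the transition; tests and the
acceptance script use 12–16 temperatures over [0.35, 0.9]).  Replicas
advance a configurable interval between exchange sweeps; each sweep
attempts every adjacent pair, alternating even/odd pairings, with the
standard acceptance min(1, exp[(β_i − β_j)(E_i − E_j)]).  Replicas start
alternately from the native conformation and from random unfolded chains:
for a knotted target the folded basin is kinetically isolated at low
temperature, and an all-unfolded initialization does not reach it within
desk budgets (measured: zero native visits and zero grid round trips with
single-pair swaps and unfolded starts).  Mixed initialization plus sweep
exchanges is the standard remedy; the first 20% of each temperature's
samples are discarded as equilibration, and grid round trips are reported
as a mixing diagnostic.

The heat capacity is Cv(T) = (⟨E²⟩ − ⟨E⟩²)/T², and the melting
temperature Tm is the grid temperature of the Cv maximum (ties to the
lower temperature).  Free-energy objects use the multiple-histogram
(WHAM) estimator: per-temperature shifts f_k are iterated in log space on
the exactly discrete energy levels to tolerance 1e−7 (cap 1e5 iterations;
non-overlapping adjacent histograms raise a diagnostic error), then every
sample is reweighted to the target temperature and binned — Q in its exact
discrete bins (multiples of 1/40), energy at integer levels, gyration
radius in 0.5 Å bins — giving F = −T ln(density), min-shifted to zero with
unsupported cells NaN.  Statistical-inefficiency corrections are omitted;
samples are thinned by the recording interval instead.

## Kinetics

A folding run starts from a seeded random unfolded conformation (uniform
chain growth with restarts, rejecting starts with Q > 0.2) and stops at
the first passage to Q = 1 or at the step budget.  Foldicity is the
fraction of runs that folded.  The rate is the negative slope of
ln P_unfolded(t) — censored runs stay unfolded through the budget — by
unweighted least squares over the window P ∈ [0.05, 1.0), refusing to fit
below a configurable floor of folded runs.  Recovery of known synthetic
rates (5% uncensored, 15% at 30% censoring, n = 2000) is the module's
acceptance surface; absolute rates of the designed structures are not
comparable to the original study's, which used 4×10⁹-MCS runs on its own
coordinates.  At desk budgets (10⁷–10⁸ MCS) the knotted protein folds
rarely — knotting is the rate-limiting step — so cross-condition
comparisons are reported as orderings (sign tests), not rate ratios.

## Ensembles and clustering

Q-binned ensembles collect trajectory snapshots with exactly Q·40 formed
native contacts, spaced at least a decorrelation gap apart within each
trajectory (default 10·N MCS; snapshots are recorded every 10–20 k MCS, so
consecutive snapshots already exceed the gap).  Shortfalls against the
requested ensemble size are reported, not fatal.  Knotting probability per
Q bin is the fraction of knotted members with binomial standard errors.

Clustering is hierarchical average linkage on the Hamming
(symmetric-difference) distance between contact maps — exact for binary
maps and scale-free here; the tree is cut at 8 clusters and clusters under
5% occupancy are merged into their nearest cluster by average distance.
Each cluster reports its per-pair contact probability map and the member
minimizing the summed distance to all members (ties to the lowest index)
as its representative.  Chaining representatives into mechanism narratives
is deliberately left to the user.

## Problem sizes

Defaults are chosen so the full test suite runs in under ten minutes and
the acceptance script in about two, on one core: replica exchange 12–16
temperatures × 6–8×10⁶ MCS; kinetics 30 runs × 2×10⁷ MCS per condition;
ensembles of 200 conformations per populated Q bin from 24–36 trajectories
× 1.2–2.5×10⁷ MCS with 10⁴-MCS snapshots.  The original experiment used 40 temperatures
× 10⁹ MCS per residue and 2000 runs × 4×10⁹ MCS; configs at that scale are
expressible (all budgets are parameters) but take CPU-months.

## What the synthetic systems do and do not show

The designed structures satisfy every printed constraint, so conclusions
that depend only on those constraints (contact counts, core location,
contact order, overlap, the lateness of knotting as a function of Q)
transfer.  The exact native geometry differs from the unpublished
original, so absolute melting temperatures, folding rates, foldicity
percentages and cluster occupancies are properties of *this* realization;
they are reported descriptively and compared only as orderings or bounds.
These are lattice Gō models throughout: no non-native energetics, no
side chains, no solvent — the same idealizations as the study being
reproduced.

## Results that are properties of this realization

Three published observations did not transfer to the spec-equivalent
structures and are reported as such (each is asserted at its published
value in the acceptance suite and left failing, with the analysis in the
test docstring):

* the 90% K/U site overlap (87.5% achieved; see above);
* the post-transition-state intermediate basin of the tethered knotted
  chain sits at Q ≈ 0.95 here, not Q = 0.75 — for this geometry every
  contact except the knot-completing ones forms readily, so the
  bottleneck, and the basin before it, lies later along Q (the basin's
  existence, the feature itself, is verified separately);
* surface tethering *lowers* the mean non-native contact count of this
  realization in Q ∈ [0.75, 0.9] instead of raising it — the wall removes
  neighbour sites, and the structural frustration that produces the
  published bump happens near this realization's own intermediate instead.

## Known limitations

* |Δ(−1)| conflates the unknot with a few higher knots whose determinant
  is 1; irrelevant for trefoil detection but a caveat for reuse.
* The closure is a single deterministic convention; conformations whose
  knot state is genuinely ambiguous (termini buried deep in the globule)
  are assigned whatever the radial closure gives, with no stochastic
  majority vote.
* The Cv peak location inherits the temperature-grid resolution (~3% at
  16 geometric points); no interpolation is attempted.
* Replica-exchange convergence at desk budgets is adequate for Tm and for
  F(Q) shapes near the transition but not for precision free-energy
  differences between deep basins.
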