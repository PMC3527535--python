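# knotfold

Monte Carlo folding of a trefoil-knotted lattice protein, in the bulk and
tethered to an inert surface.

About 1% of solved protein structures carry a knot in their backbone, most
often the trefoil (3₁), and how such chains manage to knot while folding is
still debated.  A productive way to probe the mechanism *in silico* is the
simple cubic-lattice Gō model: each residue is a bead on a lattice vertex,
bonds are unit steps, and the energy is the contact Hamiltonian

    H = ε · Σ_{i<j} Δ(i, j),        ε = −1,

where Δ(i, j) = 1 exactly when beads i and j form a contact of the native
structure (non-bonded nearest neighbours, |i − j| ≥ 3).  Folding progress is
tracked by Q, the fraction of native contacts formed, and knottedness by
closing the chain, shrinking it with Koniaris–Muthukumar–Taylor (KMT)
vertex deletions and evaluating the Alexander determinant |Δ(−1)|
(1 = unknot, 3 = trefoil).

This package implements that entire pipeline as a tested library:

* **structure design** — the two model systems exist in the literature only
  as printed constraints, so `knotfold.designer` searches for
  spec-equivalent lattice structures: *protein K* (41 beads, 40 native
  contacts, trefoil with minimal knotted segment at beads 3–22 carrying 8
  contacts, absolute contact order ≈ 17.2, compact body with the first
  terminus extended) and *protein U*, its unknotted 40-bead control
  (40 contacts, contact order 16).  The successful products ship as
  fixtures with their search seeds.
* **Monte Carlo engine** — Metropolis dynamics over corner flips, end moves
  and crankshafts (numba-compiled, ~10⁷ attempted moves/s), with three
  setups: bulk, a terminus tethered one lattice spacing above a purely
  steric wall (which also removes that terminus's end move), and a
  point tether without the wall.
* **thermodynamics** — replica exchange over a geometric temperature grid,
  heat capacity from energy fluctuations, melting temperature Tm at the
  Cv peak, and WHAM free-energy profiles F(Q) and surfaces F(E, Rg).
* **kinetics** — first-passage times to Q = 1, foldicity (fraction of runs
  that fold within budget), and the single-exponential rate from the
  survival curve ln P_unfolded(t).
* **knot analysis** — deterministic radial chain closure, exact-arithmetic
  KMT reduction, Alexander classification, knotted-core localization by
  end deletion, and knotting-probability curves p_knot(Q).
* **ensembles** — Q-binned decorrelated conformations, hierarchical
  clustering on contact-map Hamming distance, per-cluster contact
  probability maps and representatives.

The `analysis/` directory holds numbered drivers that run the study end to
end at desk-scale budgets and write tables under `results/`.

## Worked example

```python
import numpy as np
from knotfold import designer, knots
from knotfold.study import SETUP_FACTORIES, estimate_tm, fold_many, \
    harvest_q_ensembles, pknot_table

K = designer.load_native("K")
print(len(K.native_map), K.knot.type_label, knots.find_knot_core(K.conformation))
# 40 trefoil (3, 22)

# melting temperature of the C-tethered chain from a replica-exchange scan
setup = SETUP_FACTORIES["tether-c"](K.n)
tm, re = estimate_tm(K, setup, seed=1, n_temps=16, steps=8_000_000)
print(round(tm, 3))
# 0.579

# knotting probability per Q bin from folding trajectories at Tm
runs = fold_many(K, setup, tm, n_runs=36, budget=25_000_000, seed=2,
                 record_interval=25_000_000, snapshot_interval=10_000)
table = pknot_table(harvest_q_ensembles(
    runs, K, [k / 40 for k in range(33)], n_per_q=200))
print(table[table.Q.isin([0.1, 0.5, 0.8])].to_string(index=False))
#   Q   n  p_knot  stderr
# 0.1 200     0.0     0.0
# 0.5 200     0.0     0.0
# 0.8 200     0.0     0.0
```

The numbers say: at its melting temperature the C-tethered knotted protein
is essentially never knotted while it still lacks 20% or more of its
native contacts — knotting is a late folding event, the central
observation this pipeline reproduces.  (Each row is 200 decorrelated
conformations with exactly that fraction of native contacts; other seeds
occasionally put a count or two of knotted members in a bin.)

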