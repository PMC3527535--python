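"""Knotting probability as a function of nativeness, p_knot(Q).

Harvests Q-binned ensembles of decorrelated conformations of protein K
from seeded trajectories at the melting temperature in each folding setup,
classifies every conformation by closure + KMT reduction + Alexander
determinant, and writes p_knot(Q) tables with binomial errors.

The expected picture: knotting is a late folding event.  In the bulk and
N-tethered setups p_knot stays below 0.1 for Q < 0.4; with the C-terminus
tethered the knot forms even later (p_knot small up to Q ~ 0.8).
"""

import os
from pathlib import Path

from knotfold import designer
from knotfold.study import (
    SETUP_FACTORIES,
    estimate_tm,
    fold_many,
    harvest_q_ensembles,
    pknot_table,
)

OUT = Path("results/knotting")
OUT.mkdir(parents=True, exist_ok=True)

N_PER_Q = int(os.environ.get("KNOTFOLD_ENS_PER_Q", 200))
N_TRAJ = int(os.environ.get("KNOTFOLD_ENS_TRAJ", 30))
STEPS = int(os.environ.get("KNOTFOLD_ENS_STEPS", 20_000_000))
SEED = 505

K = designer.load_native("K")
n_native = len(K.native_map)

for sname in ["bulk", "tether-c", "tether-n"]:
    setup = SETUP_FACTORIES[sname](K.n)
    tm, _ = estimate_tm(K, setup, seed=SEED + 7)
    runs = fold_many(K, setup, tm, N_TRAJ, STEPS, SEED, record_interval=STEPS,
                     snapshot_interval=20_000)
    q_values = [k / n_native for k in range(0, n_native + 1)]
    ensembles = harvest_q_ensembles(runs, K, q_values, N_PER_Q)
    table = pknot_table(ensembles)
    table.to_csv(OUT / f"p_knot_{sname}.tsv", sep="\t", index=False)
    low = table[table.Q < 0.4]
    print(
        f"{sname}: Tm={tm:.3f}; max p_knot over Q<0.4 = "
        f"{low.p_knot.max() if len(low) else float('nan'):.3f} "
        f"(bins populated: {len(table)})"
    )
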