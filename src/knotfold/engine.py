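"""Monte Carlo folding engine: fixed-temperature runs and replica exchange.

The inner loop is a numba kernel operating on an occupancy grid, advancing
one elementary move attempt (1 MCS) at a time: corner flips and end moves
displace one bead, crankshafts displace two interior beads; infeasible
attempts count as rejected steps.  Energy is tracked incrementally as
minus the number of formed native contacts (epsilon = -1).  Identical
(native, params, seed) inputs give bit-identical trajectories.

Tethered setups fix the anchored bead at (0, 0, 1); the plane tether adds
a purely steric wall at z = 0 (every bead keeps z >= 1) and, like the
point tether, removes the anchored terminus's end move.  Point tethers at
other anchor sites are simulated in a frame translated so the anchor sits
at (0, 0, 1); recorded observables are frame-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .designer import NativeStructure
from .lattice import (
    LATTICE_SPACING_ANGSTROM,
    FoldingSetup,
    GeometryError,
    LatticeConformation,
    fraction_native,
    grow_self_avoiding_chain,
)

__all__ = [
    "RunParams",
    "FoldingResult",
    "ReplicaExchangeRun",
    "run_folding",
    "run_replica_exchange",
    "build_temperature_grid",
    "write_trajectory",
    "read_trajectory",
]


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


_INV53 = 1.0 / 9007199254740992.0
_U64 = np.uint64


@njit(cache=True, inline="always")
def _xs(state):
    """xorshift64 step (nonzero state)."""
    state ^= (state << _U64(13)) & _U64(0xFFFFFFFFFFFFFFFF)
    state ^= state >> _U64(7)
    state ^= (state << _U64(17)) & _U64(0xFFFFFFFFFFFFFFFF)
    return state


@njit(cache=True, inline="always")
def _seed_state(seed):
    """splitmix64 mix of a 32-bit seed into a nonzero xorshift state."""
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, inline="always")
def _scan_contacts(grid, native, b, x, y, z, off):
    """(native, total) contacts bead b would have at site (x, y, z)."""
    nat = 0
    tot = 0
    for d in range(6):
        dx = (d == 0) - (d == 1)
        dy = (d == 2) - (d == 3)
        dz = (d == 4) - (d == 5)
        j = grid[x + dx + off, y + dy + off, z + dz + off]
        if j > 0:
            jj = j - 1
            sep = jj - b if jj > b else b - jj
            if sep >= 3:
                tot += 1
                nat += native[b, jj]
    return nat, tot


@njit(cache=True)
def _run_kernel(
    pos,
    native,
    n_native_total,
    temperature,
    n_steps,
    seed,
    p_crank,
    anchored,
    wall,
    stop_at_full,
    record_interval,
    rec_time,
    rec_nat,
    rec_tot,
    rec_rg2,
    snap_interval,
    snap_time,
    snap_nat,
    snap_tot,
    snap_pos,
    t_offset,
):
    state = _seed_state(seed)
    n = pos.shape[0]
    off = n + 4
    side = 2 * n + 9
    grid = np.zeros((side, side, side), np.int8)

    # recentre a drifting bulk chain so the grid always contains it
    if anchored < 0:
        sx, sy, sz = pos[0, 0], pos[0, 1], pos[0, 2]
        for k in range(n):
            pos[k, 0] -= sx
            pos[k, 1] -= sy
            pos[k, 2] -= sz
    for k in range(n):
        grid[pos[k, 0] + off, pos[k, 1] + off, pos[k, 2] + off] = k + 1

    nat = 0
    tot = 0
    for k in range(n):
        a, t = _scan_contacts(grid, native, k, pos[k, 0], pos[k, 1], pos[k, 2], off)
        nat += a
        tot += t
    nat //= 2
    tot //= 2

    n_rec = 0
    n_snap = 0
    fpt = np.int64(-1)
    steps_done = np.int64(0)
    cands = np.empty((6, 3), np.int64)

    for step in range(n_steps):
        steps_done = step + 1
        # --- one elementary move attempt ---
        state = _xs(state)
        if float(state >> _U64(11)) * _INV53 < p_crank:
            state = _xs(state)
            i = int(float(state >> _U64(11)) * _INV53 * (n - 3))
            dx = pos[i + 3, 0] - pos[i, 0]
            dy = pos[i + 3, 1] - pos[i, 1]
            dz = pos[i + 3, 2] - pos[i, 2]
            if abs(dx) + abs(dy) + abs(dz) == 1:
                ux = pos[i + 1, 0] - pos[i, 0]
                uy = pos[i + 1, 1] - pos[i, 1]
                uz = pos[i + 1, 2] - pos[i, 2]
                vx = dy * uz - dz * uy
                vy = dz * ux - dx * uz
                vz = dx * uy - dy * ux
                n_c = 0
                for w in range(3):
                    if w == 0:
                        wx, wy, wz = -ux, -uy, -uz
                    elif w == 1:
                        wx, wy, wz = vx, vy, vz
                    else:
                        wx, wy, wz = -vx, -vy, -vz
                    ax = pos[i, 0] + wx
                    ay = pos[i, 1] + wy
                    az = pos[i, 2] + wz
                    bx, by, bz = ax + dx, ay + dy, az + dz
                    if wall and (az < 1 or bz < 1):
                        continue
                    ga = grid[ax + off, ay + off, az + off]
                    gb = grid[bx + off, by + off, bz + off]
                    # sites held by the moving beads themselves count as free
                    if (ga != 0 and ga != i + 2 and ga != i + 3) or (
                        gb != 0 and gb != i + 2 and gb != i + 3
                    ):
                        continue
                    cands[n_c, 0] = ax
                    cands[n_c, 1] = ay
                    cands[n_c, 2] = az
                    n_c += 1
                if n_c > 0:
                    state = _xs(state)
                    pick = int(float(state >> _U64(11)) * _INV53 * n_c)
                    ax = cands[pick, 0]
                    ay = cands[pick, 1]
                    az = cands[pick, 2]
                    bx, by, bz = ax + dx, ay + dy, az + dz
                    o1x, o1y, o1z = pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2]
                    o2x, o2y, o2z = pos[i + 2, 0], pos[i + 2, 1], pos[i + 2, 2]
                    grid[o1x + off, o1y + off, o1z + off] = 0
                    grid[o2x + off, o2y + off, o2z + off] = 0
                    l1n, l1t = _scan_contacts(grid, native, i + 1, o1x, o1y, o1z, off)
                    l2n, l2t = _scan_contacts(grid, native, i + 2, o2x, o2y, o2z, off)
                    g1n, g1t = _scan_contacts(grid, native, i + 1, ax, ay, az, off)
                    grid[ax + off, ay + off, az + off] = i + 2
                    g2n, g2t = _scan_contacts(grid, native, i + 2, bx, by, bz, off)
                    dnat = g1n + g2n - l1n - l2n
                    de = -float(dnat)
                    state = _xs(state)
                    if de <= 0.0 or float(state >> _U64(11)) * _INV53 < np.exp(-de / temperature):
                        grid[bx + off, by + off, bz + off] = i + 3
                        pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2] = ax, ay, az
                        pos[i + 2, 0], pos[i + 2, 1], pos[i + 2, 2] = bx, by, bz
                        nat += dnat
                        tot += g1t + g2t - l1t - l2t
                    else:
                        grid[ax + off, ay + off, az + off] = 0
                        grid[o1x + off, o1y + off, o1z + off] = i + 2
                        grid[o2x + off, o2y + off, o2z + off] = i + 3
        else:
            state = _xs(state)
            b = int(float(state >> _U64(11)) * _INV53 * n)
            if b != anchored:
                nx = np.int64(0)
                ny = np.int64(0)
                nz = np.int64(0)
                feasible = False
                if b == 0 or b == n - 1:
                    piv = 1 if b == 0 else n - 2
                    n_c = 0
                    for d in range(6):
                        cx = pos[piv, 0] + (d == 0) - (d == 1)
                        cy = pos[piv, 1] + (d == 2) - (d == 3)
                        cz = pos[piv, 2] + (d == 4) - (d == 5)
                        if wall and cz < 1:
                            continue
                        if grid[cx + off, cy + off, cz + off] != 0:
                            continue
                        cands[n_c, 0] = cx
                        cands[n_c, 1] = cy
                        cands[n_c, 2] = cz
                        n_c += 1
                    if n_c > 0:
                        state = _xs(state)
                        pick = int(float(state >> _U64(11)) * _INV53 * n_c)
                        nx = cands[pick, 0]
                        ny = cands[pick, 1]
                        nz = cands[pick, 2]
                        feasible = True
                else:
                    u1x = pos[b, 0] - pos[b - 1, 0]
                    u1y = pos[b, 1] - pos[b - 1, 1]
                    u1z = pos[b, 2] - pos[b - 1, 2]
                    u2x = pos[b + 1, 0] - pos[b, 0]
                    u2y = pos[b + 1, 1] - pos[b, 1]
                    u2z = pos[b + 1, 2] - pos[b, 2]
                    if u1x != u2x or u1y != u2y or u1z != u2z:
                        nx = pos[b - 1, 0] + u2x
                        ny = pos[b - 1, 1] + u2y
                        nz = pos[b - 1, 2] + u2z
                        if (not wall or nz >= 1) and grid[
                            nx + off, ny + off, nz + off
                        ] == 0:
                            feasible = True
                if feasible:
                    ox, oy, oz = pos[b, 0], pos[b, 1], pos[b, 2]
                    grid[ox + off, oy + off, oz + off] = 0
                    ln, lt = _scan_contacts(grid, native, b, ox, oy, oz, off)
                    gn, gt = _scan_contacts(grid, native, b, nx, ny, nz, off)
                    dnat = gn - ln
                    de = -float(dnat)
                    state = _xs(state)
                    if de <= 0.0 or float(state >> _U64(11)) * _INV53 < np.exp(-de / temperature):
                        grid[nx + off, ny + off, nz + off] = b + 1
                        pos[b, 0], pos[b, 1], pos[b, 2] = nx, ny, nz
                        nat += dnat
                        tot += gt - lt
                        if anchored < 0 and b == 0 and (
                            abs(nx) > 3 or abs(ny) > 3 or abs(nz) > 3
                        ):
                            # recentre the drifting bulk chain
                            sx, sy, sz = pos[0, 0], pos[0, 1], pos[0, 2]
                            for k in range(n):
                                grid[
                                    pos[k, 0] + off, pos[k, 1] + off, pos[k, 2] + off
                                ] = 0
                            for k in range(n):
                                pos[k, 0] -= sx
                                pos[k, 1] -= sy
                                pos[k, 2] -= sz
                            for k in range(n):
                                grid[
                                    pos[k, 0] + off, pos[k, 1] + off, pos[k, 2] + off
                                ] = k + 1
                    else:
                        grid[ox + off, oy + off, oz + off] = b + 1

        # --- bookkeeping ---
        t_now = t_offset + step + 1
        if record_interval > 0 and t_now % record_interval == 0 and n_rec < rec_time.shape[0]:
            rec_time[n_rec] = t_now
            rec_nat[n_rec] = nat
            rec_tot[n_rec] = tot
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for k in range(n):
                cx += pos[k, 0]
                cy += pos[k, 1]
                cz += pos[k, 2]
            cx /= n
            cy /= n
            cz /= n
            s2 = 0.0
            for k in range(n):
                s2 += (
                    (pos[k, 0] - cx) ** 2
                    + (pos[k, 1] - cy) ** 2
                    + (pos[k, 2] - cz) ** 2
                )
            rec_rg2[n_rec] = s2 / n
            n_rec += 1
        if snap_interval > 0 and t_now % snap_interval == 0 and n_snap < snap_time.shape[0]:
            snap_time[n_snap] = t_now
            snap_nat[n_snap] = nat
            snap_tot[n_snap] = tot
            for k in range(n):
                snap_pos[n_snap, k, 0] = pos[k, 0]
                snap_pos[n_snap, k, 1] = pos[k, 1]
                snap_pos[n_snap, k, 2] = pos[k, 2]
            n_snap += 1
        if stop_at_full and nat == n_native_total:
            fpt = t_now
            break

    return n_rec, n_snap, fpt, nat, tot, steps_done


# ---------------------------------------------------------------------------
# Parameters and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunParams:
    """Parameters of one fixed-temperature folding run."""

    temperature: float
    max_steps: int
    record_interval: int
    seed: int
    setup: FoldingSetup = FoldingSetup.bulk()
    p_crank: float = 0.2
    snapshot_interval: int = 0  # 0 disables conformation snapshots
    stop_at_q1: bool = True  # False: keep sampling after reaching the native

    def __post_init__(self):
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if not (0 < self.record_interval <= self.max_steps):
            raise ValueError("record_interval must be in (0, max_steps]")
        if not (0.0 <= self.p_crank < 1.0):
            raise ValueError("p_crank must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class FoldingResult:
    """Trajectory and outcome of one folding run."""

    params: RunParams
    trajectory: pd.DataFrame  # time, energy, Q, Rg_angstrom, n_nonnative
    folded: bool
    first_passage_time: Optional[int]
    n_steps: int
    snapshots: Optional[np.ndarray] = None  # (n_snap, N, 3) int16
    snapshot_time: Optional[np.ndarray] = None
    snapshot_nat: Optional[np.ndarray] = None
    snapshot_tot: Optional[np.ndarray] = None


def _kernel_seed(base: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=base, spawn_key=key).generate_state(1)[0]
        % (2**31 - 1)
    )


def _native_matrix(native: NativeStructure) -> np.ndarray:
    n = native.n
    mat = np.zeros((n, n), dtype=np.uint8)
    for i, j in native.native_map:
        mat[i - 1, j - 1] = 1
        mat[j - 1, i - 1] = 1
    return mat


def _internal_frame(pos: np.ndarray, setup: FoldingSetup, n: int) -> np.ndarray:
    """Translate a point-tether anchor to the internal (0, 0, 1) site."""
    if setup.mode != "point_tether" or tuple(setup.anchor_site) == (0, 0, 1):
        return pos.copy()
    k = setup.anchored_index(n)
    return pos - pos[k] + np.array((0, 0, 1), dtype=np.int64)


def generate_unfolded_start(
    native: NativeStructure,
    setup: FoldingSetup,
    rng: np.random.Generator,
    max_q: float = 0.2,
    max_tries: int = 200,
) -> LatticeConformation:
    """Random self-avoiding start with Q <= max_q under the setup."""
    for _ in range(max_tries):
        conf = grow_self_avoiding_chain(native.n, rng, setup)
        if fraction_native(conf, native.native_map) <= max_q:
            return conf
    raise GeometryError("could not generate an unfolded starting conformation")


def run_folding(
    native: NativeStructure,
    params: RunParams,
    start: Optional[LatticeConformation] = None,
) -> FoldingResult:
    """One Metropolis folding run from a random unfolded conformation.

    Stops at the first passage to Q = 1 or at the step budget.  Records a
    trajectory row every ``record_interval`` MCS and, if requested, a
    conformation snapshot every ``snapshot_interval`` MCS.
    """
    rng = np.random.default_rng(_kernel_seed(params.seed, 0))
    setup = params.setup
    if start is None:
        start = generate_unfolded_start(native, setup, rng)
    setup.check(start)
    pos = _internal_frame(start.positions.astype(np.int64), setup, native.n)

    native_mat = _native_matrix(native)
    n_native = len(native.native_map)
    max_rec = params.max_steps // params.record_interval + 2
    rec_time = np.zeros(max_rec, np.int64)
    rec_nat = np.zeros(max_rec, np.int64)
    rec_tot = np.zeros(max_rec, np.int64)
    rec_rg2 = np.zeros(max_rec, np.float64)
    if params.snapshot_interval > 0:
        max_snap = params.max_steps // params.snapshot_interval + 2
    else:
        max_snap = 1
    snap_time = np.zeros(max_snap, np.int64)
    snap_nat = np.zeros(max_snap, np.int64)
    snap_tot = np.zeros(max_snap, np.int64)
    snap_pos = np.zeros((max_snap, native.n, 3), np.int16)

    n_rec, n_snap, fpt, nat, tot, steps = _run_kernel(
        pos,
        native_mat,
        n_native,
        params.temperature,
        params.max_steps,
        _kernel_seed(params.seed, 1),
        params.p_crank,
        setup.anchored_index(native.n),
        setup.wall,
        params.stop_at_q1,
        params.record_interval,
        rec_time,
        rec_nat,
        rec_tot,
        rec_rg2,
        params.snapshot_interval,
        snap_time,
        snap_nat,
        snap_tot,
        snap_pos,
        0,
    )
    q = rec_nat[:n_rec] / n_native
    traj = pd.DataFrame(
        {
            "time": rec_time[:n_rec],
            "energy": -rec_nat[:n_rec].astype(float),
            "Q": q,
            "Rg_angstrom": np.sqrt(rec_rg2[:n_rec]) * LATTICE_SPACING_ANGSTROM,
            "n_nonnative": rec_tot[:n_rec] - rec_nat[:n_rec],
        }
    )
    return FoldingResult(
        params=params,
        trajectory=traj,
        folded=fpt >= 0,
        first_passage_time=int(fpt) if fpt >= 0 else None,
        n_steps=int(steps),
        snapshots=snap_pos[:n_snap] if params.snapshot_interval > 0 else None,
        snapshot_time=snap_time[:n_snap] if params.snapshot_interval > 0 else None,
        snapshot_nat=snap_nat[:n_snap] if params.snapshot_interval > 0 else None,
        snapshot_tot=snap_tot[:n_snap] if params.snapshot_interval > 0 else None,
    )


# ---------------------------------------------------------------------------
# Replica exchange
# ---------------------------------------------------------------------------


def build_temperature_grid(t_low: float, t_high: float, n: int = 40) -> np.ndarray:
    """Geometrically spaced temperature grid bracketing the expected Tm."""
    if not (0 < t_low < t_high):
        raise ValueError("need 0 < t_low < t_high")
    if n < 2:
        raise ValueError("need at least two temperatures")
    return np.geomspace(t_low, t_high, n)


@dataclass
class ReplicaExchangeRun:
    """Samples and diagnostics of one parallel-tempering simulation."""

    temperatures: np.ndarray
    #: per-temperature DataFrames: time, energy, Q, Rg_angstrom, n_nonnative
    samples: list[pd.DataFrame]
    exchange_interval: int
    swap_acceptance: np.ndarray  # per adjacent pair
    n_round_trips: int
    equilibration_fraction: float
    n_native: int
    seed: int

    def production(self, k: int) -> pd.DataFrame:
        """Samples at temperature index k after the equilibration cut."""
        df = self.samples[k]
        cut = int(len(df) * self.equilibration_fraction)
        return df.iloc[cut:]


def _place_native(native: NativeStructure, setup: FoldingSetup) -> Optional[np.ndarray]:
    """Native coordinates in the setup frame, or None if no placement fits.

    Under a tether the anchored bead is moved to (0, 0, 1); with a wall the
    24 proper rotations are searched for one that keeps every bead at
    z >= 1, which exists exactly when the anchored terminus lies on a face
    of the structure.
    """
    pos = native.conformation.positions.astype(np.int64)
    if setup.mode == "bulk":
        return pos.copy()
    n = native.n
    k = setup.anchored_index(n)
    anchor = np.array((0, 0, 1), dtype=np.int64)
    if not setup.wall:
        return pos - pos[k] + anchor
    from .lattice import PROPER_ROTATIONS

    for rot in PROPER_ROTATIONS:
        rp = pos @ rot.T
        rp = rp - rp[k] + anchor
        if rp[:, 2].min() >= 1:
            return rp
    return None


def run_replica_exchange(
    native: NativeStructure,
    temperatures: Sequence[float],
    steps_per_replica: int,
    seed: int,
    setup: FoldingSetup = FoldingSetup.bulk(),
    exchange_interval: int = 20_000,
    record_interval: int = 2_000,
    p_crank: float = 0.2,
    equilibration_fraction: float = 0.2,
) -> ReplicaExchangeRun:
    """Parallel tempering across a temperature grid.

    Replicas advance ``exchange_interval`` MCS between swap sweeps; each
    sweep proposes every adjacent temperature pair (alternating even/odd
    pairings) with the standard acceptance min(1, exp[(b_i - b_j)(E_i -
    E_j)]).  Replicas start alternately from the native conformation and
    from random unfolded chains so both folding basins are represented
    from the outset; the equilibration cut discards the early samples.
    Round trips of replicas between the two grid ends are counted as a
    mixing diagnostic.
    """
    temps = np.asarray(temperatures, dtype=float)
    if not np.all(np.diff(temps) >= 0):
        raise ValueError("temperature grid must be sorted increasing")
    n_t = len(temps)
    rng = np.random.default_rng(_kernel_seed(seed, 9999))
    native_mat = _native_matrix(native)
    n_native = len(native.native_map)
    n = native.n

    native_pos = _place_native(native, setup)
    states = []
    for k in range(n_t):
        if k % 2 == 0 and native_pos is not None:
            states.append(native_pos.copy())
        else:
            conf = generate_unfolded_start(native, setup, rng)
            states.append(_internal_frame(conf.positions.astype(np.int64), setup, n))
    energies = np.zeros(n_t)

    n_chunks = steps_per_replica // exchange_interval
    max_rec = exchange_interval // record_interval + 2
    buf_time = np.zeros(max_rec, np.int64)
    buf_nat = np.zeros(max_rec, np.int64)
    buf_tot = np.zeros(max_rec, np.int64)
    buf_rg2 = np.zeros(max_rec, np.float64)
    dummy_snap_t = np.zeros(1, np.int64)
    dummy_snap_n = np.zeros(1, np.int64)
    dummy_snap_c = np.zeros(1, np.int64)
    dummy_snap_p = np.zeros((1, n, 3), np.int16)

    rows: list[list[tuple]] = [[] for _ in range(n_t)]
    attempts = np.zeros(n_t - 1)
    accepts = np.zeros(n_t - 1)
    anchored = setup.anchored_index(n)

    # replica-identity tracking for round-trip statistics
    replica_at = np.arange(n_t)  # replica index currently at temperature slot
    direction = np.zeros(n_t, dtype=int)  # per replica: +1 rising, -1 falling
    round_trips = 0

    for chunk in range(n_chunks):
        for k in range(n_t):
            n_rec, _, _, nat, tot, _ = _run_kernel(
                states[k],
                native_mat,
                n_native,
                temps[k],
                exchange_interval,
                _kernel_seed(seed, k, chunk),
                p_crank,
                anchored,
                setup.wall,
                False,
                record_interval,
                buf_time,
                buf_nat,
                buf_tot,
                buf_rg2,
                0,
                dummy_snap_t,
                dummy_snap_n,
                dummy_snap_c,
                dummy_snap_p,
                chunk * exchange_interval,
            )
            energies[k] = -float(nat)
            for r in range(n_rec):
                rows[k].append(
                    (
                        buf_time[r],
                        -float(buf_nat[r]),
                        buf_nat[r] / n_native,
                        float(np.sqrt(buf_rg2[r])) * LATTICE_SPACING_ANGSTROM,
                        int(buf_tot[r] - buf_nat[r]),
                    )
                )
        # swap sweep over adjacent pairs, alternating even/odd pairings
        for i in range(chunk % 2, n_t - 1, 2):
            j = i + 1
            attempts[i] += 1
            delta = (1.0 / temps[i] - 1.0 / temps[j]) * (energies[i] - energies[j])
            if delta >= 0 or rng.random() < np.exp(delta):
                accepts[i] += 1
                states[i], states[j] = states[j], states[i]
                energies[i], energies[j] = energies[j], energies[i]
                replica_at[i], replica_at[j] = replica_at[j], replica_at[i]
        # round-trip bookkeeping
        r_lo = replica_at[0]
        r_hi = replica_at[n_t - 1]
        if direction[r_lo] == -1:
            round_trips += 1
        direction[r_lo] = 1
        if direction[r_hi] == 1:
            direction[r_hi] = -1

    samples = [
        pd.DataFrame(
            rows[k], columns=["time", "energy", "Q", "Rg_angstrom", "n_nonnative"]
        )
        for k in range(n_t)
    ]
    with np.errstate(invalid="ignore"):
        acc = np.where(attempts > 0, accepts / np.maximum(attempts, 1), np.nan)
    return ReplicaExchangeRun(
        temperatures=temps,
        samples=samples,
        exchange_interval=exchange_interval,
        swap_acceptance=acc,
        n_round_trips=round_trips,
        equilibration_fraction=equilibration_fraction,
        n_native=n_native,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Trajectory files
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["time", "energy", "Q", "Rg_angstrom", "n_nonnative", "knotted"]


def write_trajectory(path, traj: pd.DataFrame) -> None:
    """TSV trajectory file; a missing 'knotted' column is written as NA."""
    df = traj.copy()
    if "knotted" not in df.columns:
        df["knotted"] = pd.NA
    df[_TRAJ_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
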