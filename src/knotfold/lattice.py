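"""Cubic-lattice chain representation, contact geometry, observables and moves.

A protein conformation is an ordered self-avoiding walk on the simple cubic
lattice: beads sit on lattice vertices, consecutive beads are one lattice
spacing apart, and no two beads share a site.  Bead indices are 1-based in
all public interfaces; by convention bead 1 is the C-terminus and bead N the
N-terminus.  One lattice spacing corresponds to the Calpha-Calpha virtual
bond length of 3.8 angstrom, used only to express the gyration radius in
angstrom.

A *contact* is a pair of non-bonded beads occupying adjacent lattice sites
with sequence separation |i - j| >= 3.  On the cubic lattice adjacent sites
lie on opposite sublattices, so contact separations are always odd.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: Lattice spacing in angstrom (Calpha-Calpha distance along the backbone).
LATTICE_SPACING_ANGSTROM = 3.8

#: The six unit steps of the simple cubic lattice.
UNIT_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

#: Minimum sequence separation for a contact.
MIN_CONTACT_SEPARATION = 3


class GeometryError(ValueError):
    """Raised when a chain violates bond-length or excluded-volume rules."""


def _proper_rotations() -> list[np.ndarray]:
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    return mats


#: The 24 proper rotations of the cubic lattice (integer matrices, det +1).
PROPER_ROTATIONS = _proper_rotations()


@dataclass(frozen=True)
class LatticeConformation:
    """An ordered self-avoiding walk on the cubic lattice.

    Parameters
    ----------
    positions
        Integer array of shape (N, 3); row k holds the coordinates of bead
        k + 1.  Validated on construction: unit bonds, excluded volume and
        N >= 4.
    """

    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("positions must be an (N, 3) integer array")
        if pos.shape[0] < 4:
            raise GeometryError("a chain needs at least 4 beads")
        steps = np.abs(np.diff(pos, axis=0)).sum(axis=1)
        bad = np.nonzero(steps != 1)[0]
        if bad.size:
            raise GeometryError(
                f"bond between beads {bad[0] + 1} and {bad[0] + 2} is not a unit step"
            )
        seen: dict[tuple, int] = {}
        for k, site in enumerate(map(tuple, pos)):
            if site in seen:
                raise GeometryError(
                    f"beads {seen[site] + 1} and {k + 1} overlap at site {site}"
                )
            seen[site] = k
        pos.flags.writeable = False
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, LatticeConformation) and np.array_equal(
            self.positions, other.positions
        )

    def __hash__(self) -> int:
        return hash(self.positions.tobytes())

    def translated(self, shift: Sequence[int]) -> "LatticeConformation":
        return LatticeConformation(self.positions + np.asarray(shift, dtype=np.int64))

    def rotated(self, rot: np.ndarray) -> "LatticeConformation":
        return LatticeConformation(self.positions @ np.asarray(rot, dtype=np.int64).T)

    def occupied(self) -> set[tuple]:
        return set(map(tuple, self.positions))


ContactMap = frozenset  # of (i, j) bead-index pairs, 1-based, i < j


def validate_contact_map(contacts: Iterable[tuple[int, int]]) -> ContactMap:
    """Normalise and validate a contact map (separation >= 3 and odd)."""
    out = set()
    for i, j in contacts:
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        sep = j - i
        if sep < MIN_CONTACT_SEPARATION:
            raise ValueError(f"contact ({i}, {j}) has separation {sep} < 3")
        if sep % 2 == 0:
            raise ValueError(
                f"contact ({i}, {j}) has even separation {sep}: impossible on the cubic lattice"
            )
        out.add((i, j))
    return frozenset(out)


def compute_contacts(conf: LatticeConformation) -> ContactMap:
    """Enumerate all contacts of a conformation.

    Returns the set of 1-based pairs (i, j), i < j, with |i - j| >= 3 whose
    beads occupy adjacent lattice sites.
    """
    pos = conf.positions
    site_of = {tuple(p): k for k, p in enumerate(pos)}
    contacts = set()
    for k, p in enumerate(pos):
        for step in UNIT_STEPS:
            q = site_of.get((p[0] + step[0], p[1] + step[1], p[2] + step[2]))
            if q is not None and q - k >= MIN_CONTACT_SEPARATION:
                contacts.add((k + 1, q + 1))
    return frozenset(contacts)


def fraction_native(conf: LatticeConformation, native: ContactMap) -> float:
    """Fraction of native contacts formed, Q in [0, 1]."""
    if not native:
        raise ValueError("native contact map is empty")
    return len(compute_contacts(conf) & native) / len(native)


def count_nonnative(conf: LatticeConformation, native: ContactMap) -> int:
    """Number of formed contacts that are not native."""
    return len(compute_contacts(conf) - native)


def radius_of_gyration(conf: LatticeConformation, angstrom: bool = True) -> float:
    """Root-mean-square bead distance from the centroid.

    Reported in angstrom by default (lattice units times 3.8 A).
    """
    pos = conf.positions.astype(float)
    centred = pos - pos.mean(axis=0)
    rg = float(np.sqrt((centred**2).sum(axis=1).mean()))
    return rg * LATTICE_SPACING_ANGSTROM if angstrom else rg


def abs_contact_order(contacts: ContactMap) -> float:
    """Absolute contact order: mean sequence separation |i - j| over contacts."""
    if not contacts:
        raise ValueError("empty contact map has no contact order")
    return sum(j - i for i, j in contacts) / len(contacts)


# ---------------------------------------------------------------------------
# Folding setups (bulk / plane tether / point tether)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldingSetup:
    """Geometric constraints of a folding experiment.

    ``plane_tether`` fixes one terminus at (0, 0, 1), one lattice spacing
    above a purely steric wall occupying the plane z = 0 (every bead must
    keep z >= 1).  ``point_tether`` fixes the terminus at ``anchor_site``
    with no wall.  The anchored bead is never displaced by any move, which
    removes the end-move of that terminus.
    """

    mode: str = "bulk"
    anchored_bead: Optional[int] = None  # 1-based: 1 or N
    anchor_site: tuple = (0, 0, 1)

    def __post_init__(self):
        if self.mode not in ("bulk", "plane_tether", "point_tether"):
            raise ValueError(f"unknown setup mode {self.mode!r}")
        if self.mode == "bulk":
            if self.anchored_bead is not None:
                raise ValueError("bulk setup has no anchored bead")
        else:
            if self.anchored_bead is None:
                raise ValueError(f"{self.mode} requires an anchored bead")
        if self.mode == "plane_tether" and tuple(self.anchor_site) != (0, 0, 1):
            raise ValueError("plane tether anchors the bead at (0, 0, 1)")
        object.__setattr__(self, "anchor_site", tuple(int(c) for c in self.anchor_site))

    @property
    def wall(self) -> bool:
        return self.mode == "plane_tether"

    @classmethod
    def bulk(cls) -> "FoldingSetup":
        return cls("bulk", None)

    @classmethod
    def plane_tether(cls, bead: int) -> "FoldingSetup":
        return cls("plane_tether", bead, (0, 0, 1))

    @classmethod
    def point_tether(cls, bead: int, site: Sequence[int] = (0, 0, 1)) -> "FoldingSetup":
        return cls("point_tether", bead, tuple(site))

    def anchored_index(self, n: int) -> int:
        """0-based index of the anchored bead, or -1 for bulk."""
        if self.anchored_bead is None:
            return -1
        if self.anchored_bead not in (1, n):
            raise ValueError("anchored bead must be a terminus (1 or N)")
        return self.anchored_bead - 1

    def check(self, conf: LatticeConformation) -> None:
        """Raise GeometryError if ``conf`` violates the setup constraints."""
        if self.mode == "bulk":
            return
        k = self.anchored_index(conf.n)
        if tuple(conf.positions[k]) != self.anchor_site:
            raise GeometryError(
                f"anchored bead {k + 1} is at {tuple(conf.positions[k])}, "
                f"expected {self.anchor_site}"
            )
        if self.wall and int(conf.positions[:, 2].min()) < 1:
            raise GeometryError("a bead penetrates the wall (z < 1)")


# ---------------------------------------------------------------------------
# Elementary move set: corner flips, end moves, crankshafts
# ---------------------------------------------------------------------------


def _candidate_ok(
    site: np.ndarray, occupied: set, setup: FoldingSetup
) -> bool:
    if setup.wall and site[2] < 1:
        return False
    return tuple(site) not in occupied


def _crankshaft_candidates(
    pos: np.ndarray, i: int, occupied: set, setup: FoldingSetup
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Feasible rotated positions of beads i+1, i+2 about the axis i -- i+3."""
    d = pos[i + 3] - pos[i]
    if np.abs(d).sum() != 1:
        return []
    u = pos[i + 1] - pos[i]
    # self-avoidance forces the U shape: pos[i+1] = pos[i] + u, u perpendicular to d
    v = np.cross(d, u)
    cands = []
    cur = {tuple(pos[i + 1]), tuple(pos[i + 2])}
    others = occupied - cur
    for w in (-u, v, -v):  # 180 deg and the two 90 deg rotations
        a = pos[i] + w
        b = a + d
        if tuple(a) in others or tuple(b) in others:
            continue
        if setup.wall and (a[2] < 1 or b[2] < 1):
            continue
        cands.append((a, b))
    return cands


def propose_move(
    conf: LatticeConformation,
    setup: FoldingSetup,
    rng: np.random.Generator,
    p_crank: float = 0.2,
) -> Optional[LatticeConformation]:
    """One elementary Monte Carlo move attempt.

    With probability ``p_crank`` a crankshaft at a uniformly chosen eligible
    position, otherwise a single-bead move at a uniformly chosen bead: an
    end-move for a (non-anchored) terminus, a corner flip for an interior
    bead.  Returns the candidate conformation, or ``None`` for an infeasible
    attempt (a "no-move", still counted as an attempted step).
    """
    pos = conf.positions
    n = conf.n
    anchored = setup.anchored_index(n)
    occupied = conf.occupied()

    if rng.random() < p_crank:
        i = int(rng.integers(0, n - 3))
        cands = _crankshaft_candidates(pos, i, occupied, setup)
        if not cands:
            return None
        a, b = cands[int(rng.integers(0, len(cands)))]
        new = pos.copy()
        new[i + 1], new[i + 2] = a, b
        return LatticeConformation(new)

    b = int(rng.integers(0, n))
    if b == anchored:
        return None  # tethering removes this terminus's end-move
    if b in (0, n - 1):
        pivot = pos[1] if b == 0 else pos[n - 2]
        free = [
            pivot + step
            for step in UNIT_STEPS
            if _candidate_ok(pivot + step, occupied, setup)
        ]
        if not free:
            return None
        new = pos.copy()
        new[b] = free[int(rng.integers(0, len(free)))]
        return LatticeConformation(new)

    u1 = pos[b] - pos[b - 1]
    u2 = pos[b + 1] - pos[b]
    if np.array_equal(u1, u2):
        return None  # collinear bonds: no corner to flip
    target = pos[b - 1] + u2
    if not _candidate_ok(target, occupied, setup):
        return None
    new = pos.copy()
    new[b] = target
    return LatticeConformation(new)


def enumerate_moves(
    conf: LatticeConformation, setup: FoldingSetup
) -> set[LatticeConformation]:
    """All conformations reachable by one legal elementary move (test oracle)."""
    pos = conf.positions
    n = conf.n
    anchored = setup.anchored_index(n)
    occupied = conf.occupied()
    out: set[LatticeConformation] = set()
    for i in range(n - 3):
        for a, b in _crankshaft_candidates(pos, i, occupied, setup):
            new = pos.copy()
            new[i + 1], new[i + 2] = a, b
            out.add(LatticeConformation(new))
    for b in (0, n - 1):
        if b == anchored:
            continue
        pivot = pos[1] if b == 0 else pos[n - 2]
        for step in UNIT_STEPS:
            if _candidate_ok(pivot + step, occupied, setup):
                new = pos.copy()
                new[b] = pivot + step
                out.add(LatticeConformation(new))
    for b in range(1, n - 1):
        if b == anchored:
            continue
        u1 = pos[b] - pos[b - 1]
        u2 = pos[b + 1] - pos[b]
        if np.array_equal(u1, u2):
            continue
        target = pos[b - 1] + u2
        if _candidate_ok(target, occupied, setup):
            new = pos.copy()
            new[b] = target
            out.add(LatticeConformation(new))
    out.discard(conf)
    return out


# ---------------------------------------------------------------------------
# Random chain generation
# ---------------------------------------------------------------------------


def grow_self_avoiding_chain(
    n: int,
    rng: np.random.Generator,
    setup: FoldingSetup = FoldingSetup.bulk(),
    max_restarts: int = 10_000,
) -> LatticeConformation:
    """Grow a random self-avoiding chain by uniform extension with restarts.

    Under a tether the anchored bead is placed first at the anchor site and
    the chain grows from it (the conformation is then rolled so bead indices
    match the setup); under a wall every site keeps z >= 1.
    """
    anchored = setup.anchored_index(n)
    start = np.array(setup.anchor_site if anchored >= 0 else (0, 0, 1), dtype=np.int64)
    for _ in range(max_restarts):
        chain = [start]
        occupied = {tuple(start)}
        ok = True
        while len(chain) < n:
            steps = [
                chain[-1] + s
                for s in UNIT_STEPS
                if tuple(chain[-1] + s) not in occupied
                and (not setup.wall or (chain[-1] + s)[2] >= 1)
            ]
            if not steps:
                ok = False
                break
            nxt = steps[int(rng.integers(0, len(steps)))]
            chain.append(nxt)
            occupied.add(tuple(nxt))
        if ok:
            pos = np.array(chain)
            if anchored == n - 1:
                pos = pos[::-1].copy()
            return LatticeConformation(pos)
    raise GeometryError(f"failed to grow a {n}-bead chain in {max_restarts} attempts")


# ---------------------------------------------------------------------------
# Plain-text conformation files
# ---------------------------------------------------------------------------


def write_conformation(path, conf: LatticeConformation) -> None:
    """Write the plain-text lattice format: 'N', then 'index x y z' lines."""
    with open(path, "w") as fh:
        fh.write(f"{conf.n}\n")
        for k, (x, y, z) in enumerate(conf.positions, start=1):
            fh.write(f"{k} {x} {y} {z}\n")


def read_conformation(path) -> LatticeConformation:
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    body = np.array(tokens[1:], dtype=np.int64).reshape(n, 4)
    if not np.array_equal(body[:, 0], np.arange(1, n + 1)):
        raise ValueError(f"{path}: bead indices must run 1..{n} in order")
    return LatticeConformation(body[:, 1:])
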