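"""Topological analysis: chain closure, KMT reduction, knot classification.

Knottedness of an open chain is only defined after closing it into a loop.
The closure used here is deterministic: each terminus is pushed radially
outward from the chain centroid onto a sphere of three times the chain's
maximal extent, and the two external points are joined by an arc on that
sphere.  The resulting closed polygon is reduced with the
Koniaris-Muthukumar-Taylor (KMT) vertex-deletion scheme and classified by
the Alexander polynomial evaluated at t = -1: |Delta(-1)| is 1 for the
unknot, 3 for the trefoil and 5 for the figure-eight knot.  That invariant
is blind to chirality, which is all this pipeline needs to separate
unknot from trefoil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _geom
from .lattice import LatticeConformation

__all__ = [
    "KnotReport",
    "close_chain",
    "kmt_reduce",
    "alexander_det",
    "knot_report",
    "is_knotted",
    "find_knot_core",
    "p_knot_curve",
]


class ClosureError(RuntimeError):
    """Raised when no simple (non-self-intersecting) closure could be built."""


@dataclass(frozen=True)
class KnotReport:
    """Per-conformation topology summary."""

    knotted: bool
    alexander_det: int
    type_label: str  # unknot | trefoil | other
    core_range: Optional[tuple[int, int]] = None  # 1-based, inclusive

    def __post_init__(self):
        label = {1: "unknot", 3: "trefoil"}.get(self.alexander_det, "other")
        if label != self.type_label:
            raise ValueError(
                f"type label {self.type_label!r} inconsistent with |Delta(-1)| = "
                f"{self.alexander_det}"
            )
        if self.knotted != (self.alexander_det != 1):
            raise ValueError("knotted flag inconsistent with Alexander determinant")


def _label(det: int) -> str:
    return {1: "unknot", 3: "trefoil"}.get(det, "other")


# ---------------------------------------------------------------------------
# Chain closure
# ---------------------------------------------------------------------------


def _slerp_arc(u1: np.ndarray, u2: np.ndarray, radius: float) -> list[np.ndarray]:
    """Unit-sphere arc from u1 to u2 (exclusive), scaled to ``radius``."""
    cosw = float(np.clip(u1 @ u2, -1.0, 1.0))
    if cosw < -0.999:  # nearly antipodal: route via a deterministic waypoint
        for axis in np.eye(3):
            mid = np.cross(u1, axis)
            if np.linalg.norm(mid) > 1e-6:
                mid /= np.linalg.norm(mid)
                break
        return _slerp_arc(u1, mid, radius) + _slerp_arc(mid, u2, radius)
    omega = math.acos(cosw)
    nseg = max(2, int(math.ceil(omega / 0.45)))
    pts = []
    if omega < 1e-9:
        return []
    for k in range(1, nseg):
        s = k / nseg
        w = (
            math.sin((1 - s) * omega) * u1 + math.sin(s * omega) * u2
        ) / math.sin(omega)
        pts.append(np.rint(w * radius).astype(np.int64))
    return pts


_JITTERS = [
    np.zeros(3),
    np.array([0.31, 0.17, -0.23]),
    np.array([-0.27, 0.33, 0.19]),
    np.array([0.11, -0.29, 0.37]),
    np.array([-0.19, -0.13, -0.31]),
]


def close_chain(conf: LatticeConformation | np.ndarray) -> np.ndarray:
    """Close an open lattice chain into a simple polygon (integer vertices).

    The polygon is returned as an (M, 3) array with an implicit edge from
    the last vertex back to the first.  Input that is already a closed
    polygon (non-unit steps, or coinciding endpoints) is rejected.
    """
    if isinstance(conf, LatticeConformation):
        pos = conf.positions
    else:
        arr = np.asarray(conf, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("expected an (N, 3) coordinate array")
        if np.array_equal(arr[0], arr[-1]):
            raise ValueError("input is already a closed polygon; closure applies to open chains")
        pos = LatticeConformation(arr).positions  # validates unit steps / SAW

    centroid = pos.mean(axis=0)
    pos = pos - np.rint(centroid).astype(np.int64)  # keep closure coordinates small
    centroid = pos.mean(axis=0)
    extent = float(np.sqrt(((pos - centroid) ** 2).sum(axis=1)).max())
    radius = 3.0 * max(extent, 2.0)

    for jit in _JITTERS:
        d1 = pos[0] - centroid + jit
        d2 = pos[-1] - centroid - jit
        n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if n1 < 1e-9 or n2 < 1e-9:
            continue  # terminus at the centroid: jitter the direction
        u1, u2 = d1 / n1, d2 / n2
        e1 = np.rint(centroid + u1 * radius).astype(np.int64)
        e2 = np.rint(centroid + u2 * radius).astype(np.int64)
        arc = _slerp_arc(u2, u1, radius)
        closure = [e2] + arc + [e1]
        # drop consecutive duplicates introduced by rounding
        dedup = [closure[0]]
        for pt in closure[1:]:
            if not np.array_equal(pt, dedup[-1]):
                dedup.append(pt)
        poly = np.vstack([pos] + dedup)
        if len({tuple(p) for p in poly}) != len(poly):
            continue
        if not _geom._polygon_self_intersects(np.ascontiguousarray(poly)):
            return poly
    raise ClosureError("could not build a simple closure for this chain")


# ---------------------------------------------------------------------------
# KMT reduction
# ---------------------------------------------------------------------------


def kmt_reduce(polygon: np.ndarray) -> np.ndarray:
    """Reduce a simple closed polygon to its KMT fixed point.

    Vertex i is deleted when the triangle (i-1, i, i+1) intersects no other
    polygon segment (collinear vertices unconditionally); iterated until no
    deletion applies.  The knot type is invariant under reduction.
    """
    return _geom.kmt_reduce_vertices(np.asarray(polygon, dtype=np.int64))


# ---------------------------------------------------------------------------
# Alexander determinant |Delta(-1)|
# ---------------------------------------------------------------------------


def _rotation_matrix(a: float, b: float, c: float) -> np.ndarray:
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    return rz @ ry @ rx


_PROJECTIONS = [
    _rotation_matrix(0.37, 0.61, 0.23),
    _rotation_matrix(1.13, 0.29, 0.83),
    _rotation_matrix(0.71, 1.07, 0.41),
    _rotation_matrix(0.19, 0.47, 1.31),
    _rotation_matrix(1.51, 0.97, 0.13),
    _rotation_matrix(0.89, 1.39, 0.67),
    _rotation_matrix(1.27, 0.53, 1.09),
    _rotation_matrix(0.43, 1.21, 0.91),
]


class _DegenerateProjection(RuntimeError):
    pass


def _point_seg_distance_2d(p, a, b) -> float:
    d = b - a
    dd = float(d @ d)
    if dd == 0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ d / dd, 0.0, 1.0))
    return float(np.hypot(*(p - a - t * d)))


def _seg_seg_distance_2d(a, b, c, d) -> float:
    return min(
        _point_seg_distance_2d(a, c, d),
        _point_seg_distance_2d(b, c, d),
        _point_seg_distance_2d(c, a, b),
        _point_seg_distance_2d(d, a, b),
    )


def _crossings_from_projection(verts: np.ndarray) -> list[tuple]:
    """List of crossings [(seg_under, t_under, seg_over, t_over)], generic."""
    m = len(verts)
    xy = verts[:, :2]
    z = verts[:, 2]
    eps = 1e-9
    crossings = []
    seg_ts: dict[int, list[float]] = {}
    for i in range(m):
        i2 = (i + 1) % m
        di = xy[i2] - xy[i]
        for j in range(i + 1, m):
            j2 = (j + 1) % m
            if j == i or j2 == i or j == i2:
                continue
            dj = xy[j2] - xy[j]
            den = di[0] * dj[1] - di[1] * dj[0]
            rel = xy[j] - xy[i]
            li = float(np.hypot(*di))
            lj = float(np.hypot(*dj))
            if abs(den) < eps * max(li * lj, 1.0):
                # (near-)parallel in projection: degenerate only if the
                # segments actually come close to touching
                if _seg_seg_distance_2d(xy[i], xy[i2], xy[j], xy[j2]) < 1e-6 * (
                    li + lj + 1.0
                ):
                    raise _DegenerateProjection("overlapping parallel projections")
                continue
            t = (rel[0] * dj[1] - rel[1] * dj[0]) / den
            s = (rel[0] * di[1] - rel[1] * di[0]) / den
            margin = 1e-7
            if -margin < t < margin or 1 - margin < t < 1 + margin:
                if -margin < s < 1 + margin:
                    raise _DegenerateProjection("crossing at a vertex")
            if -margin < s < margin or 1 - margin < s < 1 + margin:
                if -margin < t < 1 + margin:
                    raise _DegenerateProjection("crossing at a vertex")
            if not (margin < t < 1 - margin and margin < s < 1 - margin):
                continue
            zi = z[i] + t * (z[i2] - z[i])
            zj = z[j] + s * (z[j2] - z[j])
            if abs(zi - zj) < 1e-9:
                raise _DegenerateProjection("strands touch in depth")
            if zi < zj:
                crossings.append((i, t, j, s))
            else:
                crossings.append((j, s, i, t))
            for seg, tt in ((i, t), (j, s)):
                seg_ts.setdefault(seg, []).append(tt)
    for seg, ts in seg_ts.items():
        ts.sort()
        for a, b in zip(ts, ts[1:]):
            if b - a < 1e-9:
                raise _DegenerateProjection("near-coincident crossings on a segment")
    return crossings


def _bareiss_det(mat: list[list[int]]) -> int:
    """Exact integer determinant (fraction-free Gaussian elimination)."""
    n = len(mat)
    if n == 0:
        return 1
    m = [row[:] for row in mat]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def _det_from_crossings(crossings: list[tuple]) -> int:
    n = len(crossings)
    if n == 0:
        return 1
    # order the under-passages along the curve; arc k runs from underpass
    # k-1 to underpass k, so underpass k joins arc k (in) to arc k+1 (out)
    order = sorted(range(n), key=lambda c: (crossings[c][0], crossings[c][1]))
    under_pos = [(crossings[c][0], crossings[c][1]) for c in order]

    def arc_of(pos: tuple) -> int:
        # index of the arc containing passage position pos
        lo = 0
        while lo < n and under_pos[lo] < pos:
            lo += 1
        return lo % n

    mat = [[0] * n for _ in range(n)]
    for k, c in enumerate(order):
        over = arc_of((crossings[c][2], crossings[c][3]))
        k1 = (k + 1) % n
        if over == k or over == k1:
            mat[k][k] += -1
            mat[k][k1] += 1
        else:
            mat[k][k] += 1
            mat[k][k1] += 1
            mat[k][over] += -2
    minor = [row[:-1] for row in mat[:-1]]
    return abs(_bareiss_det(minor))


def alexander_det(polygon: np.ndarray, reduce_first: bool = True) -> int:
    """|Delta(-1)| of a simple closed polygon.

    Projects along deterministically perturbed directions, builds the
    crossing diagram and evaluates the Alexander matrix at t = -1; the
    first three non-degenerate projections must agree.
    """
    poly = np.asarray(polygon, dtype=np.int64)
    if reduce_first:
        poly = kmt_reduce(poly)
    if len(poly) <= 3:
        return 1
    results = []
    for rot in _PROJECTIONS:
        verts = poly.astype(float) @ rot.T
        try:
            det = _det_from_crossings(_crossings_from_projection(verts))
        except _DegenerateProjection:
            continue
        results.append(det)
        if len(results) == 3:
            break
    if len(results) < 3:
        raise RuntimeError("no three non-degenerate projections found")
    if len(set(results)) != 1:
        raise RuntimeError(f"projections disagree on |Delta(-1)|: {results}")
    return results[0]


# ---------------------------------------------------------------------------
# Per-conformation reports
# ---------------------------------------------------------------------------


def is_knotted(conf: LatticeConformation | np.ndarray) -> bool:
    """Close, reduce and classify: True iff |Delta(-1)| != 1."""
    return alexander_det(close_chain(conf)) != 1


def knot_report(
    conf: LatticeConformation, locate_core: bool = False
) -> KnotReport:
    det = alexander_det(close_chain(conf))
    core = find_knot_core(conf) if (locate_core and det != 1) else None
    return KnotReport(
        knotted=det != 1, alexander_det=det, type_label=_label(det), core_range=core
    )


def _subchain_knotted(pos: np.ndarray, s: int, e: int) -> bool:
    if e - s + 1 < 6:  # too short to hold any knot
        return False
    return alexander_det(close_chain(pos[s : e + 1])) != 1


def find_knot_core(conf: LatticeConformation) -> Optional[tuple[int, int]]:
    """Minimal contiguous bead range whose closed sub-chain stays knotted.

    Beads are deleted one at a time from alternating ends, re-closing and
    re-testing after each deletion, until deleting from either end unknots
    the sub-chain.  Returns a 1-based inclusive range, or ``None`` for an
    unknotted input.
    """
    pos = conf.positions
    s, e = 0, conf.n - 1
    if not _subchain_knotted(pos, s, e):
        return None
    progress = True
    while progress:
        progress = False
        if _subchain_knotted(pos, s + 1, e):
            s += 1
            progress = True
        if _subchain_knotted(pos, s, e - 1):
            e -= 1
            progress = True
    return (s + 1, e + 1)


def p_knot_curve(
    ensembles: dict[float, Sequence[LatticeConformation]]
) -> pd.DataFrame:
    """Per-Q knotting probability with binomial standard errors.

    ``ensembles`` maps a Q value to its conformations; empty groups are
    omitted.  Returns a DataFrame with columns Q, n, p_knot, stderr.
    """
    rows = []
    for q in sorted(ensembles):
        group = ensembles[q]
        if not len(group):
            continue
        flags = [is_knotted(c) for c in group]
        n = len(flags)
        p = sum(flags) / n
        rows.append(
            {"Q": q, "n": n, "p_knot": p, "stderr": math.sqrt(p * (1 - p) / n)}
        )
    return pd.DataFrame(rows, columns=["Q", "n", "p_knot", "stderr"])
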