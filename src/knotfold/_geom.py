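"""Exact integer geometry predicates and KMT chain reduction.

Two parallel implementations of the same predicates live here:

* numba-jitted kernels on int64 coordinates — the hot path used for
  ensemble knot classification.  They are exact as long as coordinates stay
  below ``SAFE_COORD_BOUND`` (the worst-case intermediate product then fits
  in int64 with margin).
* pure-Python twins on arbitrary-precision integers — used automatically
  for polygons with larger coordinates, and as an independent oracle in
  tests.

A vertex of a closed polygon may be deleted (KMT step) when the closed
triangle formed with its two neighbours is not intersected by any other
polygon segment; segments sharing a corner with the triangle block deletion
only if they meet the triangle beyond the shared corner.  Collinear
vertices are deleted unconditionally.  Deletion never changes the knot
type, so iterating to a fixed point shrinks the polygon onto the segment
that carries its entanglement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Coordinate bound under which the int64 kernels cannot overflow.
SAFE_COORD_BOUND = 100


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _cross(ax, ay, az, bx, by, bz):
    return ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx


@njit(cache=True)
def _point_in_tri(nx, ny, nz, px, py, pz, qx, qy, qz, rx, ry, rz, vx, vy, vz):
    """Coplanar point v inside the closed triangle (p, q, r) with normal n."""
    c1x, c1y, c1z = _cross(qx - px, qy - py, qz - pz, vx - px, vy - py, vz - pz)
    if nx * c1x + ny * c1y + nz * c1z < 0:
        return False
    c2x, c2y, c2z = _cross(rx - qx, ry - qy, rz - qz, vx - qx, vy - qy, vz - qz)
    if nx * c2x + ny * c2y + nz * c2z < 0:
        return False
    c3x, c3y, c3z = _cross(px - rx, py - ry, pz - rz, vx - rx, vy - ry, vz - rz)
    if nx * c3x + ny * c3y + nz * c3z < 0:
        return False
    return True


@njit(cache=True)
def _coplanar_seg_seg(nx, ny, nz, ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """Closed segments (a,b) and (c,d), both in the plane with normal n."""
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = dx - cx, dy - cy, dz - cz

    c1x, c1y, c1z = _cross(ux, uy, uz, cx - ax, cy - ay, cz - az)
    o1 = nx * c1x + ny * c1y + nz * c1z
    c2x, c2y, c2z = _cross(ux, uy, uz, dx - ax, dy - ay, dz - az)
    o2 = nx * c2x + ny * c2y + nz * c2z
    c3x, c3y, c3z = _cross(vx, vy, vz, ax - cx, ay - cy, az - cz)
    o3 = nx * c3x + ny * c3y + nz * c3z
    c4x, c4y, c4z = _cross(vx, vy, vz, bx - cx, by - cy, bz - cz)
    o4 = nx * c4x + ny * c4y + nz * c4z

    if ((o1 > 0 and o2 < 0) or (o1 < 0 and o2 > 0)) and (
        (o3 > 0 and o4 < 0) or (o3 < 0 and o4 > 0)
    ):
        return True
    # collinear / endpoint-touching cases: on-segment tests
    if o1 == 0:
        t = ux * (cx - ax) + uy * (cy - ay) + uz * (cz - az)
        if 0 <= t <= ux * ux + uy * uy + uz * uz:
            return True
    if o2 == 0:
        t = ux * (dx - ax) + uy * (dy - ay) + uz * (dz - az)
        if 0 <= t <= ux * ux + uy * uy + uz * uz:
            return True
    if o3 == 0:
        t = vx * (ax - cx) + vy * (ay - cy) + vz * (az - cz)
        if 0 <= t <= vx * vx + vy * vy + vz * vz:
            return True
    if o4 == 0:
        t = vx * (bx - cx) + vy * (by - cy) + vz * (bz - cz)
        if 0 <= t <= vx * vx + vy * vy + vz * vz:
            return True
    return False


@njit(cache=True)
def _tri_seg_blocked(
    px, py, pz, qx, qy, qz, rx, ry, rz, ax, ay, az, bx, by, bz, shared
):
    """Does closed segment (a, b) obstruct deletion over triangle (p, q, r)?

    ``shared`` = 0: no common endpoint; the segment blocks if it meets the
    closed triangle at all.  ``shared`` = 1: endpoint ``a`` is the triangle
    corner p; ``shared`` = 2: endpoint ``a`` is corner r.  A shared segment
    blocks only if it meets the triangle beyond the shared corner.
    The triangle must be non-degenerate.
    """
    nx, ny, nz = _cross(qx - px, qy - py, qz - pz, rx - px, ry - py, rz - pz)
    da = nx * (ax - px) + ny * (ay - py) + nz * (az - pz)
    db = nx * (bx - px) + ny * (by - py) + nz * (bz - pz)

    if shared != 0:
        # a is a triangle corner, so da == 0
        if db != 0:
            return False  # meets the plane only at the shared corner
        # coplanar: does the segment leave the corner into the triangle?
        if shared == 1:
            u1x, u1y, u1z = qx - px, qy - py, qz - pz
            u2x, u2y, u2z = rx - px, ry - py, rz - pz
        else:
            u1x, u1y, u1z = px - rx, py - ry, pz - rz
            u2x, u2y, u2z = qx - rx, qy - ry, qz - rz
        wx, wy, wz = bx - ax, by - ay, bz - az
        cax, cay, caz = _cross(u1x, u1y, u1z, wx, wy, wz)
        if nx * cax + ny * cay + nz * caz < 0:
            return False
        cbx, cby, cbz = _cross(wx, wy, wz, u2x, u2y, u2z)
        if nx * cbx + ny * cby + nz * cbz < 0:
            return False
        return True

    if (da > 0 and db > 0) or (da < 0 and db < 0):
        return False
    if da == 0 and db == 0:
        # segment lies in the triangle plane
        if _point_in_tri(nx, ny, nz, px, py, pz, qx, qy, qz, rx, ry, rz, ax, ay, az):
            return True
        if _point_in_tri(nx, ny, nz, px, py, pz, qx, qy, qz, rx, ry, rz, bx, by, bz):
            return True
        if _coplanar_seg_seg(nx, ny, nz, ax, ay, az, bx, by, bz, px, py, pz, qx, qy, qz):
            return True
        if _coplanar_seg_seg(nx, ny, nz, ax, ay, az, bx, by, bz, qx, qy, qz, rx, ry, rz):
            return True
        if _coplanar_seg_seg(nx, ny, nz, ax, ay, az, bx, by, bz, rx, ry, rz, px, py, pz):
            return True
        return False
    if da == 0:
        return _point_in_tri(
            nx, ny, nz, px, py, pz, qx, qy, qz, rx, ry, rz, ax, ay, az
        )
    if db == 0:
        return _point_in_tri(
            nx, ny, nz, px, py, pz, qx, qy, qz, rx, ry, rz, bx, by, bz
        )

    # proper plane crossing at x = (da*b - db*a) / (da - db); scale by s
    s = da - db
    xx = da * bx - db * ax
    xy = da * by - db * ay
    xz = da * bz - db * az
    sgn = 1 if s > 0 else -1
    c1x, c1y, c1z = _cross(
        qx - px, qy - py, qz - pz, xx - s * px, xy - s * py, xz - s * pz
    )
    if sgn * (nx * c1x + ny * c1y + nz * c1z) < 0:
        return False
    c2x, c2y, c2z = _cross(
        rx - qx, ry - qy, rz - qz, xx - s * qx, xy - s * qy, xz - s * qz
    )
    if sgn * (nx * c2x + ny * c2y + nz * c2z) < 0:
        return False
    c3x, c3y, c3z = _cross(
        px - rx, py - ry, pz - rz, xx - s * rx, xy - s * ry, xz - s * rz
    )
    if sgn * (nx * c3x + ny * c3y + nz * c3z) < 0:
        return False
    return True


@njit(cache=True)
def _kmt_kernel(v):
    """One fixed-point KMT reduction of the closed polygon ``v`` (M, 3).

    Returns the boolean mask of surviving vertices.
    """
    m0 = v.shape[0]
    nxt = np.empty(m0, np.int64)
    prv = np.empty(m0, np.int64)
    for k in range(m0):
        nxt[k] = (k + 1) % m0
        prv[k] = (k - 1) % m0
    alive = np.ones(m0, np.bool_)
    m = m0
    changed = True
    while changed and m > 3:
        changed = False
        i = 0
        visited = 0
        # walk the cycle once per pass
        start = -1
        for k in range(m0):
            if alive[k]:
                start = k
                break
        i = start
        while visited < m0 and m > 3:
            visited += 1
            if not alive[i]:
                i = (i + 1) % m0
                continue
            p = prv[i]
            q = nxt[i]
            # triangle (P, B, C) = (v[p], v[i], v[q])
            e1x, e1y, e1z = v[i, 0] - v[p, 0], v[i, 1] - v[p, 1], v[i, 2] - v[p, 2]
            e2x, e2y, e2z = v[q, 0] - v[p, 0], v[q, 1] - v[p, 1], v[q, 2] - v[p, 2]
            cnx, cny, cnz = _cross(e1x, e1y, e1z, e2x, e2y, e2z)
            if cnx == 0 and cny == 0 and cnz == 0:
                blocked = False  # collinear: delete unconditionally
            else:
                blocked = False
                u = q
                while True:
                    w = nxt[u]
                    if u == q:
                        # segment (v[q], v[w]) shares corner v[q] (= r)
                        if w != p and _tri_seg_blocked(
                            v[p, 0], v[p, 1], v[p, 2],
                            v[i, 0], v[i, 1], v[i, 2],
                            v[q, 0], v[q, 1], v[q, 2],
                            v[q, 0], v[q, 1], v[q, 2],
                            v[w, 0], v[w, 1], v[w, 2],
                            2,
                        ):
                            blocked = True
                    elif w == p:
                        # segment (v[u], v[p]) shares corner v[p]
                        if _tri_seg_blocked(
                            v[p, 0], v[p, 1], v[p, 2],
                            v[i, 0], v[i, 1], v[i, 2],
                            v[q, 0], v[q, 1], v[q, 2],
                            v[p, 0], v[p, 1], v[p, 2],
                            v[u, 0], v[u, 1], v[u, 2],
                            1,
                        ):
                            blocked = True
                    else:
                        if _tri_seg_blocked(
                            v[p, 0], v[p, 1], v[p, 2],
                            v[i, 0], v[i, 1], v[i, 2],
                            v[q, 0], v[q, 1], v[q, 2],
                            v[u, 0], v[u, 1], v[u, 2],
                            v[w, 0], v[w, 1], v[w, 2],
                            0,
                        ):
                            blocked = True
                    if blocked:
                        break
                    u = w
                    if u == p:
                        break
            if not blocked:
                alive[i] = False
                nxt[p] = q
                prv[q] = p
                m -= 1
                changed = True
            i = (i + 1) % m0
    return alive


@njit(cache=True)
def _segments_intersect(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """Do the closed 3D segments (a, b) and (c, d) share any point?"""
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = dx - cx, dy - cy, dz - cz
    wx, wy, wz = cx - ax, cy - ay, cz - az
    nx, ny, nz = _cross(ux, uy, uz, vx, vy, vz)
    if nx != 0 or ny != 0 or nz != 0:
        if wx * nx + wy * ny + wz * nz != 0:
            return False  # skew lines
        den = nx * nx + ny * ny + nz * nz
        cwx, cwy, cwz = _cross(wx, wy, wz, vx, vy, vz)
        tnum = cwx * nx + cwy * ny + cwz * nz
        cux, cuy, cuz = _cross(wx, wy, wz, ux, uy, uz)
        snum = cux * nx + cuy * ny + cuz * nz
        return 0 <= tnum <= den and 0 <= snum <= den
    # parallel
    cpx, cpy, cpz = _cross(ux, uy, uz, wx, wy, wz)
    if cpx != 0 or cpy != 0 or cpz != 0:
        return False  # distinct parallel lines
    uu = ux * ux + uy * uy + uz * uz
    if uu == 0:
        return False
    t0 = ux * wx + uy * wy + uz * wz
    t1 = ux * (dx - ax) + uy * (dy - ay) + uz * (dz - az)
    lo = min(t0, t1)
    hi = max(t0, t1)
    return not (hi < 0 or lo > uu)


@njit(cache=True)
def _polygon_self_intersects(v):
    """Any pair of non-adjacent edges of closed polygon v sharing a point?"""
    m = v.shape[0]
    for i in range(m):
        i2 = (i + 1) % m
        for j in range(i + 2, m):
            j2 = (j + 1) % m
            if j2 == i:
                continue
            if _segments_intersect(
                v[i, 0], v[i, 1], v[i, 2], v[i2, 0], v[i2, 1], v[i2, 2],
                v[j, 0], v[j, 1], v[j, 2], v[j2, 0], v[j2, 1], v[j2, 2],
            ):
                return True
    return False


# ---------------------------------------------------------------------------
# pure-Python twins (arbitrary precision; oracle and large-coordinate path)
# ---------------------------------------------------------------------------


def _pycross(a, b):
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _pydot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _pysub(a, b):
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _py_point_in_tri(n, p, q, r, v):
    for s, e in ((p, q), (q, r), (r, p)):
        if _pydot(n, _pycross(_pysub(e, s), _pysub(v, s))) < 0:
            return False
    return True


def _py_coplanar_seg_seg(n, a, b, c, d):
    u = _pysub(b, a)
    v = _pysub(d, c)
    o1 = _pydot(n, _pycross(u, _pysub(c, a)))
    o2 = _pydot(n, _pycross(u, _pysub(d, a)))
    o3 = _pydot(n, _pycross(v, _pysub(a, c)))
    o4 = _pydot(n, _pycross(v, _pysub(b, c)))
    if ((o1 > 0 > o2) or (o1 < 0 < o2)) and ((o3 > 0 > o4) or (o3 < 0 < o4)):
        return True
    uu = _pydot(u, u)
    vv = _pydot(v, v)
    if o1 == 0 and 0 <= _pydot(u, _pysub(c, a)) <= uu:
        return True
    if o2 == 0 and 0 <= _pydot(u, _pysub(d, a)) <= uu:
        return True
    if o3 == 0 and 0 <= _pydot(v, _pysub(a, c)) <= vv:
        return True
    if o4 == 0 and 0 <= _pydot(v, _pysub(b, c)) <= vv:
        return True
    return False


def _py_tri_seg_blocked(p, q, r, a, b, shared):
    n = _pycross(_pysub(q, p), _pysub(r, p))
    da = _pydot(n, _pysub(a, p))
    db = _pydot(n, _pysub(b, p))
    if shared != 0:
        if db != 0:
            return False
        if shared == 1:
            u1, u2 = _pysub(q, p), _pysub(r, p)
        else:
            u1, u2 = _pysub(p, r), _pysub(q, r)
        w = _pysub(b, a)
        if _pydot(n, _pycross(u1, w)) < 0:
            return False
        if _pydot(n, _pycross(w, u2)) < 0:
            return False
        return True
    if (da > 0 and db > 0) or (da < 0 and db < 0):
        return False
    if da == 0 and db == 0:
        if _py_point_in_tri(n, p, q, r, a) or _py_point_in_tri(n, p, q, r, b):
            return True
        for s, e in ((p, q), (q, r), (r, p)):
            if _py_coplanar_seg_seg(n, a, b, s, e):
                return True
        return False
    if da == 0:
        return _py_point_in_tri(n, p, q, r, a)
    if db == 0:
        return _py_point_in_tri(n, p, q, r, b)
    s = da - db
    x = tuple(da * bb - db * aa for aa, bb in zip(a, b))
    sgn = 1 if s > 0 else -1
    for pp, qq in ((p, q), (q, r), (r, p)):
        edge = _pysub(qq, pp)
        rel = tuple(xc - s * pc for xc, pc in zip(x, pp))
        if sgn * _pydot(n, _pycross(edge, rel)) < 0:
            return False
    return True


def _py_kmt(verts):
    """Pure-Python KMT fixed point; verts is a list of int 3-tuples."""
    v = list(verts)
    changed = True
    while changed and len(v) > 3:
        changed = False
        i = 0
        while i < len(v) and len(v) > 3:
            m = len(v)
            p, b, q = v[i - 1], v[i], v[(i + 1) % m]
            n = _pycross(_pysub(b, p), _pysub(q, p))
            if n == (0, 0, 0):
                blocked = False
            else:
                blocked = False
                for j in range(m):
                    j2 = (j + 1) % m
                    if j == (i - 1) % m or j == i:
                        continue
                    if j2 == (i - 1) % m:
                        blocked = _py_tri_seg_blocked(p, b, q, p, v[j], 1)
                    elif j == (i + 1) % m:
                        blocked = _py_tri_seg_blocked(p, b, q, q, v[j2], 2)
                    else:
                        blocked = _py_tri_seg_blocked(p, b, q, v[j], v[j2], 0)
                    if blocked:
                        break
            if not blocked:
                del v[i]
                changed = True
            else:
                i += 1
    return v


def kmt_reduce_vertices(v: np.ndarray) -> np.ndarray:
    """KMT-reduce a closed polygon to its fixed point (knot type preserved).

    Chooses the jitted int64 kernel when coordinates are small enough for
    exact arithmetic, the arbitrary-precision Python path otherwise.
    """
    v = np.ascontiguousarray(v, dtype=np.int64)
    if v.shape[0] <= 3:
        return v
    if np.abs(v).max() <= SAFE_COORD_BOUND:
        alive = _kmt_kernel(v)
        return v[alive]
    reduced = _py_kmt([tuple(int(c) for c in row) for row in v])
    return np.array(reduced, dtype=np.int64)
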