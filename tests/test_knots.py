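"""Closure, KMT reduction, Alexander classification, core localization."""

import numpy as np
import pytest

from knotfold import fixtures
from knotfold._geom import _py_kmt, kmt_reduce_vertices
from knotfold.knots import (
    KnotReport,
    alexander_det,
    close_chain,
    find_knot_core,
    is_knotted,
    kmt_reduce,
    knot_report,
    p_knot_curve,
)
from knotfold.lattice import PROPER_ROTATIONS, LatticeConformation

from conftest import straight_rod


_UNIT6 = [np.array(u) for u in
          ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))]


def _corner_flip_polygon(v, i, occupied):
    m = len(v)
    a, b, c = v[i - 1], v[i], v[(i + 1) % m]
    u1, u2 = b - a, c - b
    if np.array_equal(u1, u2):
        return None
    target = tuple(a + u2)
    if target in occupied:
        return None
    out = v.copy()
    out[i] = target
    return out


def _insert_staple_polygon(v, i, w, occupied):
    a, b = v[i], v[(i + 1) % len(v)]
    if int(w @ (b - a)) != 0:
        return None
    na, nb = tuple(a + w), tuple(b + w)
    if na in occupied or nb in occupied:
        return None
    return np.insert(v, i + 1, [na, nb], axis=0)


def random_closed_polygon(length, rng, base=None):
    """Random closed self-avoiding lattice polygon of a known knot type.

    Grown from ``base`` (default: the unit square, an unknot) by staple
    insertions and shuffled by corner flips; both moves sweep a unit
    lattice square that no other edge can pierce, so the knot type of the
    base is preserved by construction.
    """
    if base is None:
        base = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=np.int64)
    v = base.copy()
    guard = 0
    while len(v) < length and guard < 50 * length:
        guard += 1
        occupied = {tuple(p) for p in v}
        if rng.random() < 0.5 and len(v) + 2 <= length:
            i = int(rng.integers(0, len(v)))
            w = _UNIT6[int(rng.integers(0, 6))]
            cand = _insert_staple_polygon(v, i, w, occupied)
        else:
            cand = _corner_flip_polygon(v, int(rng.integers(0, len(v))), occupied)
        if cand is not None:
            v = cand
    for _ in range(3 * length):  # extra shuffling at final length
        occupied = {tuple(p) for p in v}
        cand = _corner_flip_polygon(v, int(rng.integers(0, len(v))), occupied)
        if cand is not None:
            v = cand
    rot = PROPER_ROTATIONS[int(rng.integers(0, 24))]
    return v @ rot.T + rng.integers(-5, 6, size=3)


@pytest.fixture(scope="module")
def trefoil24():
    return fixtures.load_polygon("trefoil")


@pytest.fixture(scope="module")
def fig8_30():
    return fixtures.load_polygon("figure_eight")


class TestClosure:
    def test_planar_u_chain_closes_unknotted(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        poly = close_chain(LatticeConformation(pos))
        assert alexander_det(poly) == 1

    def test_native_k_closes_as_trefoil(self, protein_k):
        poly = close_chain(protein_k.conformation)
        assert alexander_det(poly) == 3

    def test_double_closure_rejected(self, protein_k):
        poly = close_chain(protein_k.conformation)
        with pytest.raises(ValueError):
            close_chain(poly)

    def test_closure_deterministic(self, protein_k):
        a = close_chain(protein_k.conformation)
        b = close_chain(protein_k.conformation)
        assert np.array_equal(a, b)


class TestKMT:
    def test_square_reduces_to_floor(self):
        square = np.array(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0], [2, 2, 0],
             [1, 2, 0], [0, 2, 0], [0, 1, 0]]
        )
        red = kmt_reduce(square)
        assert len(red) <= 4
        assert alexander_det(red) == 1

    def test_trefoil_fixture_det_before_and_after(self, trefoil24):
        assert alexander_det(trefoil24, reduce_first=False) == 3
        red = kmt_reduce(trefoil24)
        assert len(red) < len(trefoil24)
        assert alexander_det(red, reduce_first=False) == 3

    def test_reduction_preserves_det_on_random_polygons(self, rng, trefoil24, fig8_30):
        """Randomized polygons of known type: det is right before and after."""
        bases = [(None, 1), (trefoil24, 3), (fig8_30, 5)]
        for k in range(120):
            base, expect = bases[k % 3]
            poly = random_closed_polygon(36, rng, base=base)
            assert alexander_det(poly, reduce_first=False) == expect
            assert alexander_det(kmt_reduce(poly), reduce_first=False) == expect

    def test_jitted_kernel_agrees_with_python_oracle(self, rng):
        """The int64 kernel and the big-integer path give identical knots."""
        for _ in range(40):
            poly = random_closed_polygon(26, rng)  # randomized unknots
            fast = kmt_reduce_vertices(poly)
            slow = np.array(_py_kmt([tuple(map(int, r)) for r in poly]), dtype=np.int64)
            assert alexander_det(fast, reduce_first=False) == alexander_det(
                slow, reduce_first=False
            )


class TestAlexander:
    def test_canonical_polygons(self, trefoil24, fig8_30):
        rectangle = np.array([[0, 0, 0], [3, 0, 0], [3, 2, 0], [0, 2, 0]])
        assert alexander_det(rectangle) == 1
        assert alexander_det(trefoil24) == 3
        assert alexander_det(fig8_30) == 5

    def test_invariance_under_lattice_symmetry(self, trefoil24):
        for rot in PROPER_ROTATIONS[::5]:
            moved = trefoil24 @ rot.T + np.array([7, -4, 11])
            assert alexander_det(moved) == 3

    def test_mirror_preserves_det(self, trefoil24, fig8_30):
        """|Delta(-1)| is chirality-blind: reflection leaves it unchanged."""
        for poly, expect in ((trefoil24, 3), (fig8_30, 5)):
            mirrored = poly.copy()
            mirrored[:, 0] *= -1
            assert alexander_det(mirrored) == expect


class TestReports:
    def test_report_labels(self, protein_k):
        rep = knot_report(protein_k.conformation)
        assert rep.knotted and rep.type_label == "trefoil" and rep.alexander_det == 3

    def test_report_consistency_enforced(self):
        with pytest.raises(ValueError):
            KnotReport(knotted=True, alexander_det=1, type_label="unknot")
        with pytest.raises(ValueError):
            KnotReport(knotted=True, alexander_det=3, type_label="unknot")

    def test_rod_is_unknotted(self):
        assert not is_knotted(straight_rod(10))


class TestCore:
    def test_unknotted_input_has_no_core(self, rod10):
        assert find_knot_core(rod10) is None

    def test_k_fixture_core(self, protein_k):
        assert find_knot_core(protein_k.conformation) == (3, 22)

    def test_whole_chain_trefoil_core_spans_everything(self, trefoil24):
        """An opened minimal trefoil with no slack keeps (almost) all beads."""
        # opening the fixture at an essential vertex leaves a knotted open chain
        for shift in range(len(trefoil24)):
            chain = np.roll(trefoil24, -shift, axis=0)[:20]
            conf = LatticeConformation(chain)
            if is_knotted(conf):
                core = find_knot_core(conf)
                assert core is not None
                lo, hi = core
                assert hi - lo + 1 >= 15  # nearly the whole sub-chain
                break
        else:
            pytest.fail("no knotted opening found")

    def test_core_agrees_with_bruteforce_on_small_chains(self, protein_k, rng):
        """End-deletion equals exhaustive smallest-window search, chains <= 30."""

        def brute(pos):
            n = len(pos)
            for size in range(6, n + 1):
                for s in range(0, n - size + 1):
                    sub = pos[s : s + size]
                    if is_knotted(LatticeConformation(sub)):
                        return (s + 1, s + size)
            return None

        # knotted sub-chains of the K fixture plus random unknotted chains
        kpos = protein_k.conformation.positions
        cases = [kpos[1:29], kpos[2:30], kpos[0:28]]
        for pos in cases:
            conf = LatticeConformation(pos)
            expected = brute(pos)
            got = find_knot_core(conf)
            assert got == expected


class TestPknotCurve:
    def test_native_group_is_fully_knotted(self, protein_k):
        df = p_knot_curve({1.0: [protein_k.conformation] * 5})
        assert df.p_knot.tolist() == [1.0]
        assert df.n.tolist() == [5]

    def test_rod_group_is_unknotted_and_empty_groups_dropped(self):
        df = p_knot_curve({0.0: [straight_rod(12)] * 3, 0.5: []})
        assert len(df) == 1
        assert df.p_knot.iloc[0] == 0.0
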