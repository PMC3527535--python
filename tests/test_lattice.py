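"""Chain geometry, contact enumeration, observables and the move set."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knotfold.lattice import (
    LATTICE_SPACING_ANGSTROM,
    PROPER_ROTATIONS,
    UNIT_STEPS,
    FoldingSetup,
    GeometryError,
    LatticeConformation,
    abs_contact_order,
    compute_contacts,
    count_nonnative,
    enumerate_moves,
    fraction_native,
    grow_self_avoiding_chain,
    propose_move,
    radius_of_gyration,
    read_conformation,
    validate_contact_map,
    write_conformation,
)

from conftest import straight_rod


def all_saws(n_steps):
    """Every self-avoiding walk of n_steps steps starting at the origin."""
    walks = [[(0, 0, 0)]]
    for _ in range(n_steps):
        nxt = []
        for w in walks:
            x, y, z = w[-1]
            for dx, dy, dz in UNIT_STEPS:
                p = (x + dx, y + dy, z + dz)
                if p not in w:
                    nxt.append(w + [p])
        walks = nxt
    return walks


class TestConformation:
    def test_broken_bond_names_offender(self):
        pos = [[0, 0, 0], [1, 0, 0], [3, 0, 0], [4, 0, 0]]
        with pytest.raises(GeometryError, match="beads 2 and 3"):
            LatticeConformation(np.array(pos))

    def test_overlap_names_offenders(self):
        pos = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]]
        with pytest.raises(GeometryError, match="overlap"):
            LatticeConformation(np.array(pos))

    def test_minimum_length(self):
        with pytest.raises(GeometryError):
            LatticeConformation(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))

    def test_file_round_trip_bit_exact(self, tmp_path, rng):
        conf = grow_self_avoiding_chain(25, rng)
        path = tmp_path / "conf.txt"
        write_conformation(path, conf)
        again = read_conformation(path)
        assert np.array_equal(conf.positions, again.positions)
        write_conformation(tmp_path / "conf2.txt", again)
        assert (tmp_path / "conf2.txt").read_text() == path.read_text()


class TestContacts:
    def test_straight_rod_has_none(self, rod10):
        assert compute_contacts(rod10) == frozenset()

    def test_exhaustive_oracle_on_all_8step_saws(self):
        """Contact enumeration equals a brute-force pairwise-distance scan."""
        for walk in all_saws(8):
            pos = np.array(walk)
            conf = LatticeConformation(pos)
            oracle = {
                (i + 1, j + 1)
                for i, j in itertools.combinations(range(len(pos)), 2)
                if j - i >= 3 and np.abs(pos[i] - pos[j]).sum() == 1
            }
            assert compute_contacts(conf) == oracle

    def test_invariant_under_rotation_and_translation(self, rng):
        conf = grow_self_avoiding_chain(30, rng)
        ref = compute_contacts(conf)
        for rot in PROPER_ROTATIONS:
            assert compute_contacts(conf.rotated(rot).translated((5, -3, 7))) == ref

    def test_contact_map_validation(self):
        with pytest.raises(ValueError, match="separation"):
            validate_contact_map([(1, 3)])
        with pytest.raises(ValueError, match="even"):
            validate_contact_map([(1, 5)])
        assert validate_contact_map([(4, 1)]) == frozenset({(1, 4)})


class TestObservables:
    def test_fraction_native_identity_and_rod(self, toy_native8, rod10):
        assert fraction_native(toy_native8.conformation, toy_native8.native_map) == 1.0
        rod8 = straight_rod(8)
        assert fraction_native(rod8, toy_native8.native_map) == 0.0

    def test_count_nonnative(self, toy_native8):
        assert count_nonnative(toy_native8.conformation, toy_native8.native_map) == 0
        # against a deliberately wrong 1-contact "native" map
        fake = frozenset({(1, 6)})
        formed = compute_contacts(toy_native8.conformation)
        assert count_nonnative(toy_native8.conformation, fake) == len(formed - fake)

    @pytest.mark.parametrize("n", [2, 5, 10, 41])
    def test_rod_rg_closed_form(self, n):
        if n < 4:
            pos = np.zeros((4, 3), dtype=np.int64)
            pos[:, 0] = np.arange(4)
            conf = LatticeConformation(pos)
            # closed form checked on the first n beads via direct formula
            sub = pos[:n].astype(float)
            rg = np.sqrt(((sub - sub.mean(0)) ** 2).sum(1).mean())
            assert rg == pytest.approx(np.sqrt((n**2 - 1) / 12.0))
            return
        conf = straight_rod(n)
        expected = LATTICE_SPACING_ANGSTROM * np.sqrt((n**2 - 1) / 12.0)
        assert radius_of_gyration(conf) == pytest.approx(expected, rel=1e-12)

    def test_rg_matches_double_loop_oracle(self, rng):
        conf = grow_self_avoiding_chain(20, rng)
        pos = conf.positions.astype(float)
        c = pos.mean(axis=0)
        oracle = np.sqrt(sum(((p - c) ** 2).sum() for p in pos) / len(pos))
        assert radius_of_gyration(conf, angstrom=False) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_abs_contact_order(self):
        assert abs_contact_order(frozenset({(1, 4), (2, 9)})) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            abs_contact_order(frozenset())


class TestMoves:
    def test_seeded_proposals_cover_exact_move_set(self, rng):
        """10^5 seeded attempts on a fixed 6-mer reach exactly the legal moves."""
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1]]
        )
        conf = LatticeConformation(pos)
        setup = FoldingSetup.bulk()
        legal = enumerate_moves(conf, setup)
        seen = set()
        for _ in range(100_000):
            cand = propose_move(conf, setup, rng)
            if cand is not None and cand != conf:
                seen.add(cand)
        assert seen == legal

    def test_reversibility_by_enumeration(self, rng):
        """Every reachable state can propose the original state back."""
        for n in (5, 6, 8):
            conf = grow_self_avoiding_chain(n, rng)
            setup = FoldingSetup.bulk()
            for cand in enumerate_moves(conf, setup):
                assert conf in enumerate_moves(cand, setup)

    def test_collinear_interior_bead_cannot_flip(self):
        rod = straight_rod(6)
        legal = enumerate_moves(rod, FoldingSetup.bulk())
        # only end moves exist for a rod: 5 vacant pivot neighbours per end
        for cand in legal:
            diff = (cand.positions != rod.positions).any(axis=1)
            assert diff.sum() == 1 and (diff[0] or diff[-1])

    def test_anchored_bead_never_moves(self, rng):
        setup = FoldingSetup.plane_tether(1)
        conf = grow_self_avoiding_chain(10, rng, setup)
        for _ in range(20_000):
            cand = propose_move(conf, setup, rng)
            if cand is not None:
                assert tuple(cand.positions[0]) == setup.anchor_site
                assert cand.positions[:, 2].min() >= 1
                conf = cand
        setup.check(conf)

    def test_wall_constraint_never_violated(self, rng):
        setup = FoldingSetup.plane_tether(8)
        conf = grow_self_avoiding_chain(8, rng, setup)
        assert tuple(conf.positions[-1]) == (0, 0, 1)
        for _ in range(20_000):
            cand = propose_move(conf, setup, rng)
            if cand is not None:
                conf = cand
        assert conf.positions[:, 2].min() >= 1

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_accepted_moves_preserve_chain_invariants(self, seed):
        rng = np.random.default_rng(seed)
        conf = grow_self_avoiding_chain(12, rng)
        for _ in range(200):
            cand = propose_move(conf, FoldingSetup.bulk(), rng)
            if cand is not None:
                conf = cand  # constructor re-validates bonds and excluded volume
        assert conf.n == 12


class TestSetups:
    def test_plane_tether_requires_standard_anchor(self):
        with pytest.raises(ValueError):
            FoldingSetup("plane_tether", 1, (2, 2, 2))

    def test_bulk_has_no_anchor(self):
        with pytest.raises(ValueError):
            FoldingSetup("bulk", 1)

    def test_check_flags_wall_violation(self):
        pos = np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0], [1, 0, 1]])
        conf = LatticeConformation(pos)
        with pytest.raises(GeometryError, match="wall"):
            FoldingSetup.plane_tether(1).check(conf)
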