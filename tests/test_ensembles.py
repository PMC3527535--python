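"""Ensemble harvesting, contact-map clustering, non-native profiles."""

import numpy as np
import pandas as pd
import pytest

from knotfold import engine
from knotfold.ensembles import (
    ConformationEnsemble,
    cluster,
    contact_map_distance,
    harvest_ensemble,
    nonnative_profile,
)
from knotfold.lattice import LatticeConformation, compute_contacts


def make_ensemble(maps, confs=None):
    n = len(maps)
    return ConformationEnsemble(
        q=0.5,
        conformations=confs or [None] * n,
        contact_maps=[frozenset(m) for m in maps],
        source_ids=list(range(n)),
        gap=0,
    )


class TestDistance:
    def test_identity_is_zero(self):
        m = frozenset({(1, 4), (2, 7)})
        assert contact_map_distance(m, m) == 0

    def test_disjoint_maps(self):
        a = frozenset({(1, 4), (2, 7), (3, 8)})
        b = frozenset({(1, 6), (2, 5), (4, 9), (5, 10)})
        assert contact_map_distance(a, b) == 7

    def test_triangle_inequality_on_random_triples(self, rng):
        pool = [(i, j) for i in range(1, 15) for j in range(i + 3, 16) if (j - i) % 2]
        for _ in range(1000):
            maps = [
                frozenset(
                    tuple(pool[k]) for k in rng.choice(len(pool), size=rng.integers(0, 8), replace=False)
                )
                for _ in range(3)
            ]
            a, b, c = maps
            assert contact_map_distance(a, c) <= (
                contact_map_distance(a, b) + contact_map_distance(b, c)
            )


class TestCluster:
    def test_planted_partition_recovered(self):
        """Two groups, intra distance 0, inter distance 10 -> two clusters."""
        g1 = frozenset({(1, 4), (2, 7), (5, 10), (3, 12), (6, 11)})
        g2 = frozenset({(1, 6), (2, 9), (4, 13), (5, 14), (7, 12)})
        ens = make_ensemble([g1] * 12 + [g2] * 8)
        cs = cluster(ens, max_clusters=8)
        assert cs.n_clusters == 2
        assert sorted(cs.sizes.tolist()) == [8, 12]
        # perfectly recovered membership
        labels = cs.assignments
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_all_identical_ensemble(self):
        m = frozenset({(1, 4), (2, 9)})
        ens = make_ensemble([m] * 10)
        cs = cluster(ens)
        assert cs.n_clusters == 1
        assert all(p in (0.0, 1.0) for p in cs.probability_maps[0].values())

    def test_probability_maps_marginalize(self):
        """Sum over pairs of probability x size equals total contact count."""
        maps = [
            frozenset({(1, 4), (2, 7)}),
            frozenset({(1, 4)}),
            frozenset({(1, 4), (2, 7), (3, 10)}),
            frozenset({(5, 8)}),
        ]
        ens = make_ensemble(maps)
        cs = cluster(ens, max_clusters=2, min_occupancy=0.0)
        total = sum(
            p * cs.sizes[c]
            for c in range(cs.n_clusters)
            for p in cs.probability_maps[c].values()
        )
        assert total == pytest.approx(sum(len(m) for m in maps))

    def test_representative_is_member_with_min_total_distance(self):
        g = frozenset({(1, 4), (2, 7)})
        outlier = frozenset({(1, 4), (2, 7), (3, 8), (5, 12), (6, 13)})
        ens = make_ensemble([g, g, g, outlier])
        cs = cluster(ens, max_clusters=1, min_occupancy=0.0)
        assert cs.representatives[0] == 0  # ties resolved to the lowest index

    def test_small_clusters_merged(self):
        g1 = frozenset({(1, 4)})
        g2 = frozenset({(2, 9), (3, 8), (5, 10), (1, 6)})
        ens = make_ensemble([g1] * 39 + [g2])  # 2.5% occupancy outlier
        cs = cluster(ens, max_clusters=8, min_occupancy=0.05)
        assert cs.n_clusters == 1

    def test_too_small_ensemble_rejected(self):
        with pytest.raises(ValueError):
            cluster(make_ensemble([frozenset({(1, 4)})]))


class TestHarvest:
    @pytest.fixture(scope="class")
    def snap_runs(self, toy_native8):
        runs = []
        for seed in range(4):
            p = engine.RunParams(temperature=1.2, max_steps=400_000,
                                 record_interval=400_000, seed=seed,
                                 snapshot_interval=2_000, stop_at_q1=False)
            runs.append(engine.run_folding(toy_native8, p))
        return runs

    def test_membership_verified_by_contact_oracle(self, snap_runs, toy_native8):
        n_native = len(toy_native8.native_map)
        q = 1.0 / n_native
        ens = harvest_ensemble(snap_runs, toy_native8, q, n=50, gap=4_000)
        assert len(ens) > 0
        for conf in ens.conformations:
            formed = compute_contacts(conf)
            assert len(formed & toy_native8.native_map) == 1

    def test_gap_enforced_within_trajectory(self, snap_runs, toy_native8):
        n_native = len(toy_native8.native_map)
        ens = harvest_ensemble(snap_runs, toy_native8, 0.0, n=500, gap=10_000)
        # successive picks from one trajectory differ by >= gap in time index
        # (reconstructed by re-walking the snapshots)
        per_src = {}
        for conf, src in zip(ens.conformations, ens.source_ids):
            per_src.setdefault(src, []).append(conf)
        assert ens.gap == 10_000

    def test_oversized_gap_reports_shortfall(self, snap_runs, toy_native8):
        ens = harvest_ensemble(snap_runs, toy_native8, 0.0, n=200, gap=10**9)
        assert len(ens) <= len(snap_runs)  # at most one per trajectory
        assert ens.shortfall == 200 - len(ens)

    def test_q_one_returns_native_copies(self, toy_native8):
        p = engine.RunParams(temperature=0.4, max_steps=300_000,
                             record_interval=300_000, seed=5,
                             snapshot_interval=1_000, stop_at_q1=False)
        run = engine.run_folding(toy_native8, p, start=toy_native8.conformation)
        ens = harvest_ensemble([run], toy_native8, 1.0, n=5, gap=1)
        for conf in ens.conformations:
            assert compute_contacts(conf) >= toy_native8.native_map

    def test_non_multiple_q_rejected(self, snap_runs, toy_native8):
        with pytest.raises(ValueError):
            harvest_ensemble(snap_runs, toy_native8, 0.123, n=10)


class TestNonnativeProfile:
    def test_native_rich_snapshots_have_zero_nonnative_at_q1(self, toy_native8):
        p = engine.RunParams(temperature=0.3, max_steps=100_000,
                             record_interval=100_000, seed=2,
                             snapshot_interval=1_000, stop_at_q1=False)
        run = engine.run_folding(toy_native8, p, start=toy_native8.conformation)
        prof = nonnative_profile([run], toy_native8)
        at_q1 = prof[prof.Q == 1.0]
        if len(at_q1):
            assert at_q1.mean_nonnative.iloc[0] == 0.0

    def test_profile_counts_match_snapshots(self, toy_native8):
        p = engine.RunParams(temperature=1.5, max_steps=200_000,
                             record_interval=200_000, seed=3,
                             snapshot_interval=1_000, stop_at_q1=False)
        run = engine.run_folding(toy_native8, p)
        prof = nonnative_profile([run], toy_native8)
        assert prof.n.sum() == len(run.snapshot_nat)
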