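"""Heat capacity, melting temperature and WHAM estimators."""

import numpy as np
import pandas as pd
import pytest

from knotfold.engine import ReplicaExchangeRun
from knotfold.thermo import (
    estimate_Tm,
    heat_capacity,
    wham,
    wham_shifts,
)


def two_level_cv(g: float, t: np.ndarray) -> np.ndarray:
    """Closed-form Cv of a two-level system with energies {0, -g}."""
    p = np.exp(g / t) / (1.0 + np.exp(g / t))  # occupancy of E = -g
    return g**2 * p * (1 - p) / t**2


def sample_two_level(g: float, t: float, n: int, rng) -> np.ndarray:
    p = np.exp(g / t) / (1.0 + np.exp(g / t))
    return np.where(rng.random(n) < p, -g, 0.0)


def fake_re_run(frames: list[pd.DataFrame], temps, n_native=10) -> ReplicaExchangeRun:
    return ReplicaExchangeRun(
        temperatures=np.asarray(temps, float),
        samples=frames,
        exchange_interval=1,
        swap_acceptance=np.array([]),
        n_round_trips=0,
        equilibration_fraction=0.0,
        n_native=n_native,
        seed=0,
    )


def frame_from_energy(e: np.ndarray, n_native=10) -> pd.DataFrame:
    nat = (-e).astype(int)
    return pd.DataFrame(
        {
            "time": np.arange(len(e)),
            "energy": e.astype(float),
            "Q": nat / n_native,
            "Rg_angstrom": 5.0 + 0.1 * nat,
            "n_nonnative": 0,
        }
    )


class TestHeatCapacity:
    def test_constant_energy_gives_zero(self):
        cv = heat_capacity({0.5: np.full(100, -3.0)})
        assert cv.Cv.iloc[0] == 0.0

    def test_two_level_matches_closed_form(self, rng):
        """Exact Boltzmann draws reproduce the analytic Cv within MC error."""
        g, n = 2.0, 200_000
        for t in (0.6, 1.0, 1.6):
            e = sample_two_level(g, t, n, rng)
            got = heat_capacity({t: e}).Cv.iloc[0]
            expect = two_level_cv(g, np.array([t]))[0]
            # delta-method standard error of var(E)/T^2 for a Bernoulli mix
            p = np.exp(g / t) / (1 + np.exp(g / t))
            se = g**2 * np.sqrt(p * (1 - p) * abs(1 - 2 * p) ** 2 / n + 2 * (p * (1 - p)) ** 2 / n) / t**2
            assert abs(got - expect) < max(5 * se, 5e-3)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            heat_capacity({0.5: np.array([1.0])})

    def test_permutation_invariance(self, rng):
        e = rng.normal(size=1000)
        a = heat_capacity({0.7: e}).Cv.iloc[0]
        b = heat_capacity({0.7: rng.permutation(e)}).Cv.iloc[0]
        assert a == pytest.approx(b, rel=1e-12)


class TestTm:
    def test_single_peak(self):
        cv = pd.DataFrame({"T": [0.4, 0.5, 0.6], "Cv": [1.0, 9.0, 2.0]})
        assert estimate_Tm(cv) == 0.5

    def test_tie_breaks_to_lower_temperature(self):
        cv = pd.DataFrame({"T": [0.4, 0.5, 0.6], "Cv": [1.0, 7.0, 7.0]})
        assert estimate_Tm(cv) == 0.5

    def test_two_level_peak_location_recovered(self, rng):
        """Cv-peak temperature of the two-level system within 10% of closed form."""
        g = 2.0
        temps = np.geomspace(0.3, 3.0, 25)
        dense = np.geomspace(0.3, 3.0, 4001)
        t_star = dense[np.argmax(two_level_cv(g, dense))]
        cv = heat_capacity(
            {t: sample_two_level(g, t, 40_000, rng) for t in temps}
        )
        assert estimate_Tm(cv) == pytest.approx(t_star, rel=0.10)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            estimate_Tm(pd.DataFrame({"T": [], "Cv": []}))


class TestWham:
    def test_single_temperature_limit_is_exact(self, rng):
        nat = rng.integers(0, 11, size=4000)
        fr = frame_from_energy(-nat.astype(float))
        re = fake_re_run([fr], [0.8])
        surf = wham(re, "q", 0.8)
        hist = np.bincount(nat, minlength=11).astype(float)
        direct = -0.8 * np.log(hist / hist.sum())
        direct -= np.nanmin(direct)
        assert np.nanmax(np.abs(surf.values - direct)) < 1e-10

    def test_shifts_invariant_under_doubling_iterations(self, rng):
        temps = [0.6, 0.8, 1.0]
        frames = [
            sample_boltzmann_discrete(t, rng, n=3000) for t in temps
        ]
        f1 = wham_shifts(frames, temps, tol=1e-9, max_iter=50_000)
        f2 = wham_shifts(frames, temps, tol=1e-9, max_iter=100_000)
        assert np.allclose(f1, f2, atol=1e-7)

    def test_reweighted_mean_energy_matches_direct_sample_mean(self, rng):
        """Reweighting to a grid temperature reproduces its own sample mean."""
        temps = [0.6, 0.8, 1.0]
        energies = [sample_boltzmann_discrete(t, rng, n=6000) for t in temps]
        frames = [frame_from_energy(e) for e in energies]
        re = fake_re_run(frames, temps)
        f = wham_shifts(energies, temps)
        from knotfold.thermo import _sample_log_weights

        for k, t in enumerate(temps):
            logw = _sample_log_weights(
                np.concatenate(energies), energies, np.array(temps), f, t
            )
            w = np.exp(logw)
            e_hat = float(np.concatenate(energies) @ w)
            direct = energies[k].mean()
            se = energies[k].std() / np.sqrt(len(energies[k]))
            assert abs(e_hat - direct) < 6 * se

    def test_nonoverlapping_histograms_diagnosed(self):
        lo = frame_from_energy(np.full(100, -9.0))
        hi = frame_from_energy(np.zeros(100))
        re = fake_re_run([lo, hi], [0.4, 2.0])
        with pytest.raises(ValueError, match="overlap"):
            wham(re, "q", 0.5)

    def test_two_level_profile_matches_exact_marginals(self, rng):
        """F over the two-level states equals -T ln of exact Boltzmann weights."""
        g, t = 2.0, 0.9
        e = sample_two_level(g, t, 300_000, rng)
        re = fake_re_run([frame_from_energy(e, n_native=int(g))], [t], n_native=int(g))
        surf = wham(re, "q", t)
        p = np.exp(g / t) / (1 + np.exp(g / t))
        exact = -t * np.log(np.array([1 - p, p]))
        exact -= exact.min()
        got = surf.values[[0, int(g)]]
        got -= np.nanmin(got)
        assert np.allclose(got, exact, atol=0.02)


def sample_boltzmann_discrete(t: float, rng, n: int, levels=None) -> np.ndarray:
    """Exact Boltzmann draws over discrete energy levels (default -5..0)."""
    if levels is None:
        levels = np.arange(-5, 1, dtype=float)
    w = np.exp(-levels / t)
    w /= w.sum()
    return rng.choice(levels, size=n, p=w)
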