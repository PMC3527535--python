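"""Folding thermodynamics: heat capacity, melting temperature, WHAM.

The heat capacity is evaluated from mean-squared energy fluctuations at
each replica-exchange temperature, Cv(T) = (<E^2> - <E>^2) / (k_B T^2)
with k_B = 1; the melting temperature is the grid temperature at which Cv
attains its maximum.  Free-energy surfaces are computed by the standard
multiple-histogram (WHAM) estimator: per-temperature free-energy shifts
are iterated to self-consistency over the exactly discrete Go energy
levels, then every sample is reweighted to the target temperature and
binned over the requested reaction coordinates; F = -T ln(density),
shifted so the minimum is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ReplicaExchangeRun

__all__ = [
    "ThermoResult",
    "FreeEnergySurface",
    "heat_capacity",
    "estimate_Tm",
    "wham_shifts",
    "wham",
    "thermo_summary",
]

logger = logging.getLogger(__name__)

#: Gyration-radius bin width (angstrom) for free-energy surfaces.
RG_BIN_ANGSTROM = 0.5


@dataclass
class FreeEnergySurface:
    """Free energy (epsilon units) over one or two reaction coordinates.

    ``values`` is min-shifted to zero; cells with no sampled support hold
    NaN rather than zero.
    """

    coords: tuple[str, ...]  # ("Q",) or ("energy", "Rg_angstrom")
    axes: tuple[np.ndarray, ...]  # bin centers per coordinate
    values: np.ndarray
    temperature: float


@dataclass
class ThermoResult:
    cv_curve: pd.DataFrame  # T, Cv
    tm: float
    surfaces: dict[str, FreeEnergySurface]


def heat_capacity(samples_by_t: dict[float, np.ndarray]) -> pd.DataFrame:
    """Cv(T) from energy fluctuations; requires >= 2 samples per T."""
    rows = []
    for t in sorted(samples_by_t):
        e = np.asarray(samples_by_t[t], dtype=float)
        if e.size < 2:
            raise ValueError(f"need at least 2 energy samples at T={t}")
        rows.append({"T": t, "Cv": e.var() / t**2})
    return pd.DataFrame(rows)


def estimate_Tm(cv_curve: pd.DataFrame) -> float:
    """Temperature of the Cv maximum; ties break to the lower temperature."""
    if not len(cv_curve):
        raise ValueError("empty heat-capacity curve")
    cv = cv_curve.sort_values("T").reset_index(drop=True)
    imax = int(cv.Cv.round(12).idxmax())  # idxmax takes the first = lowest T
    ties = np.isclose(cv.Cv, cv.Cv[imax]).sum()
    if ties > 1:
        logger.info("Cv maximum is %d-fold degenerate; taking the lowest T", ties)
    return float(cv["T"][imax])


def _re_energy_samples(re_run: ReplicaExchangeRun) -> list[np.ndarray]:
    return [re_run.production(k).energy.to_numpy() for k in range(len(re_run.temperatures))]


def heat_capacity_from_re(re_run: ReplicaExchangeRun) -> pd.DataFrame:
    return heat_capacity(
        {
            float(t): e
            for t, e in zip(re_run.temperatures, _re_energy_samples(re_run))
            if e.size >= 2
        }
    )


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


def wham_shifts(
    energies: Sequence[np.ndarray],
    temperatures: Sequence[float],
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Self-consistent dimensionless free-energy shifts f_k per temperature.

    Iterates the standard multiple-histogram equations on the discrete
    energy levels until every shift moves by less than ``tol``.  Adjacent
    temperatures must have overlapping energy histograms.
    """
    temps = np.asarray(temperatures, float)
    betas = 1.0 / temps
    n_k = np.array([len(e) for e in energies], float)
    if np.any(n_k == 0):
        raise ValueError("every temperature needs at least one sample")

    all_e = np.concatenate([np.asarray(e, float) for e in energies])
    levels, counts = np.unique(all_e, return_counts=True)

    # overlap diagnostic: consecutive temperatures must share energy levels
    for k in range(len(energies) - 1):
        lo = set(np.unique(energies[k]))
        hi = set(np.unique(energies[k + 1]))
        if not lo & hi:
            raise ValueError(
                f"energy histograms at T={temps[k]:.4g} and T={temps[k+1]:.4g} "
                "do not overlap; densify the temperature grid"
            )

    # log-space iteration:  -beta_k E  (n_levels, n_temps)
    neg_be = -np.outer(levels, betas)
    log_counts = np.log(counts)
    log_nk = np.log(n_k)
    f = np.zeros(len(temps))
    for _ in range(max_iter):
        # log Omega(E) = log H(E) - logsumexp_k [log N_k + f_k - beta_k E]
        denom = log_nk[None, :] + f[None, :] + neg_be
        log_omega = log_counts - _logsumexp(denom, axis=1)
        # f_k = -log sum_E Omega(E) e^{-beta_k E}
        f_new = -_logsumexp(log_omega[:, None] + neg_be, axis=0)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            return f_new
        f = f_new
    raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def _sample_log_weights(
    energies_flat: np.ndarray,
    per_t_energies: Sequence[np.ndarray],
    temperatures: np.ndarray,
    f: np.ndarray,
    t_target: float,
) -> np.ndarray:
    betas = 1.0 / np.asarray(temperatures, float)
    n_k = np.array([len(e) for e in per_t_energies], float)
    denom = _logsumexp(
        np.log(n_k)[None, :] + f[None, :] - np.outer(energies_flat, betas), axis=1
    )
    logw = -energies_flat / t_target - denom
    return logw - _logsumexp(logw, axis=0)


def wham(
    re_run: ReplicaExchangeRun,
    coords: str = "q",
    t_target: Optional[float] = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FreeEnergySurface:
    """Free-energy surface at ``t_target`` from replica-exchange samples.

    ``coords`` is ``"q"`` for the one-dimensional profile over the
    fraction of native contacts (exactly discrete bins, multiples of
    1/n_native) or ``"e-rg"`` for the surface over energy (discrete
    integer levels) and gyration radius (0.5-angstrom bins).
    """
    temps = re_run.temperatures
    frames = [re_run.production(k) for k in range(len(temps))]
    energies = [fr.energy.to_numpy() for fr in frames]
    if t_target is None:
        t_target = estimate_Tm(heat_capacity_from_re(re_run))
    f = wham_shifts(energies, temps, tol=tol, max_iter=max_iter)

    e_flat = np.concatenate(energies)
    logw = _sample_log_weights(e_flat, energies, temps, f, t_target)
    w = np.exp(logw)

    if coords == "q":
        nq = re_run.n_native
        q_flat = np.concatenate([fr.Q.to_numpy() for fr in frames])
        idx = np.rint(q_flat * nq).astype(int)
        dens = np.bincount(idx, weights=w, minlength=nq + 1)
        with np.errstate(divide="ignore"):
            fe = np.where(dens > 0, -t_target * np.log(dens), np.nan)
        fe -= np.nanmin(fe)
        axes = (np.arange(nq + 1) / nq,)
        return FreeEnergySurface(("Q",), axes, fe, t_target)

    if coords == "e-rg":
        rg_flat = np.concatenate([fr.Rg_angstrom.to_numpy() for fr in frames])
        e_levels = np.arange(e_flat.min(), e_flat.max() + 1)
        e_idx = (e_flat - e_flat.min()).astype(int)
        rg_idx = np.floor(rg_flat / RG_BIN_ANGSTROM).astype(int)
        rg_lo = rg_idx.min()
        rg_idx -= rg_lo
        dens = np.zeros((len(e_levels), rg_idx.max() + 1))
        np.add.at(dens, (e_idx, rg_idx), w)
        with np.errstate(divide="ignore"):
            fe = np.where(dens > 0, -t_target * np.log(dens), np.nan)
        fe -= np.nanmin(fe)
        rg_centers = (np.arange(dens.shape[1]) + rg_lo + 0.5) * RG_BIN_ANGSTROM
        return FreeEnergySurface(("energy", "Rg_angstrom"), (e_levels, rg_centers), fe, t_target)

    raise ValueError("coords must be 'q' or 'e-rg'")


def thermo_summary(re_run: ReplicaExchangeRun, coords: tuple[str, ...] = ("q",)) -> ThermoResult:
    """Cv curve, Tm, and the requested free-energy objects at Tm."""
    cv = heat_capacity_from_re(re_run)
    tm = estimate_Tm(cv)
    surfaces = {c: wham(re_run, c, tm) for c in coords}
    return ThermoResult(cv_curve=cv, tm=tm, surfaces=surfaces)
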