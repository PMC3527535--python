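"""Folding kinetics: first-passage times, foldicity, single-exponential rate.

Each folding run either reaches the native state (recording its first
passage time, in MCS) or exhausts its step budget (a censored run).
Foldicity is the fraction of runs that folded.  The folding rate is the
negative slope of ln P_unfolded(t) — the survival fraction of runs still
unfolded at time t — fitted by unweighted least squares over the window
where P_unfolded lies in [0.05, 1.0); censored runs stay unfolded through
the budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import FoldingResult, RunParams

__all__ = ["KineticsResult", "collect_fpts", "survival_curve", "fit_rate"]


@dataclass
class KineticsResult:
    fpt_list: np.ndarray  # first-passage times of folded runs (MCS)
    n_attempted: int
    n_folded: int
    budget: int  # MCS budget shared by all runs
    rate: Optional[float] = None  # 1/MCS
    fit_r2: Optional[float] = None
    fit_window: Optional[tuple[float, float]] = None
    fit_status: str = "not fitted"

    @property
    def foldicity(self) -> float:
        return self.n_folded / self.n_attempted

    def __post_init__(self):
        self.fpt_list = np.sort(np.asarray(self.fpt_list, dtype=np.int64))
        if len(self.fpt_list) != self.n_folded:
            raise ValueError("fpt_list length must equal n_folded")
        if self.n_folded > self.n_attempted:
            raise ValueError("more folded than attempted runs")


def _params_key(p: RunParams) -> tuple:
    return (p.temperature, p.max_steps, p.record_interval, p.setup, p.p_crank)


def collect_fpts(results: Sequence[FoldingResult]) -> KineticsResult:
    """Aggregate first-passage times from runs sharing all params but the seed."""
    if not results:
        raise ValueError("no runs to aggregate")
    keys = {_params_key(r.params) for r in results}
    if len(keys) > 1:
        raise ValueError("runs mix different parameters; aggregate per condition")
    fpts = [r.first_passage_time for r in results if r.folded]
    return KineticsResult(
        fpt_list=np.array(fpts, dtype=np.int64),
        n_attempted=len(results),
        n_folded=len(fpts),
        budget=results[0].params.max_steps,
    )


def survival_curve(result: KineticsResult, n_grid: int = 400) -> pd.DataFrame:
    """P_unfolded(t) on a uniform time grid spanning (0, budget]."""
    ts = np.linspace(0, result.budget, n_grid + 1)[1:]
    folded_by_t = np.searchsorted(result.fpt_list, ts, side="right")
    p_unfolded = 1.0 - folded_by_t / result.n_attempted
    return pd.DataFrame({"time": ts, "P_unfolded": p_unfolded})


def fit_rate(
    result: KineticsResult,
    min_folded: int = 50,
    p_floor: float = 0.05,
    n_grid: int = 400,
) -> KineticsResult:
    """Least-squares slope of ln P_unfolded(t); k = -slope.

    Censored runs contribute to the survival up to the budget; the fit
    window is capped below at ``p_floor`` to avoid tail noise.  Refuses to
    fit (status explains why) with fewer than ``min_folded`` folded runs.
    """
    if result.n_folded < min_folded:
        result.rate = None
        result.fit_status = (
            f"refused: {result.n_folded} folded runs < floor {min_folded}"
        )
        return result
    curve = survival_curve(result, n_grid=n_grid)
    mask = (curve.P_unfolded >= p_floor) & (curve.P_unfolded < 1.0)
    pts = curve[mask]
    if len(pts) < 2 or pts.P_unfolded.nunique() < 2:
        result.rate = None
        result.fit_status = "refused: survival curve has no usable decay window"
        return result
    x = pts.time.to_numpy()
    y = np.log(pts.P_unfolded.to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    result.rate = -float(slope)
    result.fit_r2 = r2
    result.fit_window = (float(x[0]), float(x[-1]))
    result.fit_status = "ok"
    return result
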