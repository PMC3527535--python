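"""End-to-end orchestration of the tethered-folding study at scaled budgets.

The full study chains: native design (or bundled fixtures) -> replica-
exchange thermodynamics (Cv, Tm, WHAM profiles) -> fixed-temperature
kinetics at Tm in every folding setup -> knotting-probability curves and
non-native-contact profiles -> contact-map clustering of the Q = 0.75
intermediate ensembles.  Budgets here are deliberately far below the
original 10^9-MCS-per-residue scale; they are configurable, and every
stage records its seed in the output manifest.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import designer, engine, kinetics as kin, knots, thermo
from .ensembles import ConformationEnsemble, harvest_ensemble, nonnative_profile
from .lattice import FoldingSetup

logger = logging.getLogger(__name__)

SETUP_FACTORIES = {
    "bulk": lambda n: FoldingSetup.bulk(),
    "tether-c": lambda n: FoldingSetup.plane_tether(1),
    "tether-n": lambda n: FoldingSetup.plane_tether(n),
    "point-c": lambda n: FoldingSetup.point_tether(1),
    "point-n": lambda n: FoldingSetup.point_tether(n),
}

DEFAULT_CONFIG = {
    "seed": 1,
    "proteins": ["K", "U"],
    "setups": ["bulk", "tether-c", "tether-n"],
    "re": {"t_low": 0.35, "t_high": 0.9, "n_temps": 16, "steps": 10_000_000},
    "kinetics": {"n_runs": 40, "budget": 30_000_000, "record_interval": 100_000},
    "ensembles": {
        "n_per_q": 200,
        "snapshot_interval": 20_000,
        "n_trajectories": 20,
        "steps": 20_000_000,
    },
    "cluster_q": 0.75,
}


def _seed_for(base: int, *key) -> int:
    """Stable sub-seed from a base seed and string/int tags (crc32, not
    Python's salted hash, so runs reproduce across processes)."""
    tags = tuple(zlib.crc32(str(k).encode()) for k in key)
    h = np.random.SeedSequence(entropy=base, spawn_key=tags)
    return int(h.generate_state(1)[0] % (2**31 - 1))


def estimate_tm(
    native: designer.NativeStructure,
    setup: FoldingSetup,
    seed: int,
    t_low: float = 0.35,
    t_high: float = 0.9,
    n_temps: int = 16,
    steps: int = 10_000_000,
) -> tuple[float, engine.ReplicaExchangeRun]:
    """Replica-exchange Cv scan; returns (Tm, RE run)."""
    grid = engine.build_temperature_grid(t_low, t_high, n_temps)
    re = engine.run_replica_exchange(native, grid, steps, seed, setup)
    tm = thermo.estimate_Tm(thermo.heat_capacity_from_re(re))
    return tm, re


def fold_many(
    native: designer.NativeStructure,
    setup: FoldingSetup,
    temperature: float,
    n_runs: int,
    budget: int,
    seed: int,
    record_interval: int = 100_000,
    snapshot_interval: int = 0,
) -> list[engine.FoldingResult]:
    """Independent seeded folding runs sharing all parameters."""
    out = []
    for r in range(n_runs):
        params = engine.RunParams(
            temperature=temperature,
            max_steps=budget,
            record_interval=record_interval,
            seed=_seed_for(seed, "run", r),
            setup=setup,
            snapshot_interval=snapshot_interval,
        )
        out.append(engine.run_folding(native, params))
    return out


def harvest_q_ensembles(
    results: Sequence[engine.FoldingResult],
    native: designer.NativeStructure,
    q_values: Sequence[float],
    n_per_q: int,
    gap: Optional[int] = None,
) -> dict[float, ConformationEnsemble]:
    return {
        q: harvest_ensemble(results, native, q, n_per_q, gap) for q in q_values
    }


def pknot_table(ensembles: dict[float, ConformationEnsemble]) -> pd.DataFrame:
    """Knotting probability per Q bin with sizes and binomial errors."""
    groups = {q: e.conformations for q, e in ensembles.items() if len(e)}
    return knots.p_knot_curve(groups)


def run_study(config: Optional[dict] = None, out_dir: Optional[Path] = None) -> dict:
    """Execute every stage of the scaled study; returns the report dict."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "stages": {}}
    t_start = time.time()

    natives = {name: designer.load_native(name) for name in cfg["proteins"]}
    report["stages"]["design"] = {
        name: {"n": s.n, "n_contacts": len(s.native_map), "knot": s.knot.type_label}
        for name, s in natives.items()
    }

    tm: dict[tuple[str, str], float] = {}
    for pname, native in natives.items():
        for sname in cfg["setups"]:
            setup = SETUP_FACTORIES[sname](native.n)
            t0 = time.time()
            tm_val, re = estimate_tm(
                native, setup, _seed_for(seed, "re", pname, sname), **cfg["re"]
            )
            tm[(pname, sname)] = tm_val
            cv = thermo.heat_capacity_from_re(re)
            fq = thermo.wham(re, "q", tm_val)
            if out_dir:
                base = out_dir / f"{pname}_{sname}"
                base.mkdir(exist_ok=True)
                cv.to_csv(base / "cv.tsv", sep="\t", index=False)
                pd.DataFrame({"Q": fq.axes[0], "F": fq.values}).to_csv(
                    base / "free_energy_q.tsv", sep="\t", index=False
                )
            report["stages"].setdefault("thermo", {})[f"{pname}/{sname}"] = {
                "Tm": tm_val,
                "duration_s": round(time.time() - t0, 1),
            }
            logger.info("Tm(%s, %s) = %.3f", pname, sname, tm_val)

    kcfg = cfg["kinetics"]
    for pname, native in natives.items():
        for sname in cfg["setups"]:
            setup = SETUP_FACTORIES[sname](native.n)
            t0 = time.time()
            runs = fold_many(
                native,
                setup,
                tm[(pname, sname)],
                kcfg["n_runs"],
                kcfg["budget"],
                _seed_for(seed, "kin", pname, sname),
                record_interval=kcfg["record_interval"],
            )
            result = kin.fit_rate(kin.collect_fpts(runs))
            if out_dir:
                base = out_dir / f"{pname}_{sname}"
                base.mkdir(exist_ok=True)
                kin.survival_curve(result).to_csv(
                    base / "survival.tsv", sep="\t", index=False
                )
            report["stages"].setdefault("kinetics", {})[f"{pname}/{sname}"] = {
                "foldicity": result.foldicity,
                "n_folded": result.n_folded,
                "rate_per_mcs": result.rate,
                "fit_status": result.fit_status,
                "duration_s": round(time.time() - t0, 1),
            }

    ecfg = cfg["ensembles"]
    native = natives.get("K")
    if native is not None:
        n_native = len(native.native_map)
        for sname in cfg["setups"]:
            setup = SETUP_FACTORIES[sname](native.n)
            t0 = time.time()
            runs = fold_many(
                native,
                setup,
                tm[("K", sname)],
                ecfg["n_trajectories"],
                ecfg["steps"],
                _seed_for(seed, "ens", sname),
                record_interval=ecfg["steps"],
                snapshot_interval=ecfg["snapshot_interval"],
            )
            q_values = [k / n_native for k in range(0, n_native + 1, 2)]
            ensembles = harvest_q_ensembles(runs, native, q_values, ecfg["n_per_q"])
            pknot = pknot_table(ensembles)
            profile = nonnative_profile(runs, native)
            if out_dir:
                base = out_dir / f"K_{sname}"
                base.mkdir(exist_ok=True)
                pknot.to_csv(base / "p_knot.tsv", sep="\t", index=False)
                profile.to_csv(base / "nonnative_profile.tsv", sep="\t", index=False)
            report["stages"].setdefault("knotting", {})[sname] = {
                "max_p_knot_lowQ": float(
                    pknot[pknot.Q < 0.4].p_knot.max() if len(pknot[pknot.Q < 0.4]) else np.nan
                ),
                "duration_s": round(time.time() - t0, 1),
            }

    report["total_duration_s"] = round(time.time() - t_start, 1)
    if out_dir:
        (out_dir / "study_report.json").write_text(
            json.dumps(report, indent=2, default=float)
        )
    return report
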