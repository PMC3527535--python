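"""Q-binned conformational ensembles, contact-map clustering, profiles.

Ensembles of decorrelated conformations with a fixed number of formed
native contacts are harvested from trajectory snapshots.  Hierarchical
average-linkage clustering on the Hamming (symmetric-difference) distance
between contact maps separates conformational classes; each cluster is
summarised by its per-pair contact probability map and by the member
closest to the cluster centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .designer import NativeStructure
from .engine import FoldingResult
from .lattice import ContactMap, LatticeConformation, compute_contacts

__all__ = [
    "ConformationEnsemble",
    "ClusterSet",
    "harvest_ensemble",
    "contact_map_distance",
    "cluster",
    "nonnative_profile",
]


@dataclass
class ConformationEnsemble:
    """Conformations sharing an exact count of formed native contacts."""

    q: float
    conformations: list[LatticeConformation]
    contact_maps: list[ContactMap]
    source_ids: list[int]  # trajectory index each member came from
    gap: int  # minimum intra-trajectory spacing (MCS)
    shortfall: int = 0  # how many below the requested size

    def __len__(self) -> int:
        return len(self.conformations)


@dataclass
class ClusterSet:
    assignments: np.ndarray  # cluster label per ensemble member (0-based)
    sizes: np.ndarray
    occupancies: np.ndarray  # sizes / ensemble size
    probability_maps: list[dict[tuple[int, int], float]]
    representatives: list[int]  # ensemble index of each cluster representative

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def contact_map_distance(a: ContactMap, b: ContactMap) -> int:
    """Hamming distance between contact maps: |a symmetric-difference b|."""
    return len(set(a) ^ set(b))


def harvest_ensemble(
    results: Sequence[FoldingResult],
    native: NativeStructure,
    q: float,
    n: int,
    gap: Optional[int] = None,
) -> ConformationEnsemble:
    """Collect up to ``n`` decorrelated snapshots with exactly q*|native| contacts.

    Snapshots from the same trajectory are kept at least ``gap`` MCS apart
    (default 10*N); a shortfall is reported, not an error.
    """
    n_native = len(native.native_map)
    target = round(q * n_native)
    if abs(target - q * n_native) > 1e-9:
        raise ValueError(f"Q={q} is not a multiple of 1/{n_native}")
    if gap is None:
        gap = 10 * native.n
    confs: list[LatticeConformation] = []
    maps: list[ContactMap] = []
    sources: list[int] = []
    for tid, res in enumerate(results):
        if res.snapshots is None:
            continue
        last_kept = -np.inf
        for s in range(len(res.snapshots)):
            if len(confs) >= n:
                break
            if res.snapshot_nat[s] != target:
                continue
            t = res.snapshot_time[s]
            if t - last_kept < gap:
                continue
            conf = LatticeConformation(res.snapshots[s].astype(np.int64))
            confs.append(conf)
            maps.append(compute_contacts(conf))
            sources.append(tid)
            last_kept = t
        if len(confs) >= n:
            break
    return ConformationEnsemble(
        q=q,
        conformations=confs,
        contact_maps=maps,
        source_ids=sources,
        gap=gap,
        shortfall=max(0, n - len(confs)),
    )


def _binary_matrix(maps: Sequence[ContactMap]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    pairs = sorted(set().union(*maps)) if maps else []
    index = {p: k for k, p in enumerate(pairs)}
    mat = np.zeros((len(maps), len(pairs)), dtype=np.uint8)
    for r, m in enumerate(maps):
        for p in m:
            mat[r, index[p]] = 1
    return mat, pairs


def cluster(
    ensemble: ConformationEnsemble,
    max_clusters: int = 8,
    min_occupancy: float = 0.05,
) -> ClusterSet:
    """Average-linkage clustering on contact-map Hamming distance.

    The tree is cut at ``max_clusters``; clusters below ``min_occupancy``
    are merged into their nearest (average-distance) cluster so the
    reported classes are the relevant ones.  Representatives minimise the
    summed distance to all members of their cluster, ties to the lowest
    ensemble index.
    """
    m = len(ensemble)
    if m < 2:
        raise ValueError("need an ensemble of at least 2 conformations")
    mat, pairs = _binary_matrix(ensemble.contact_maps)
    if mat.shape[1] == 0:
        labels = np.zeros(m, dtype=int)
    else:
        condensed = pdist(mat, metric="cityblock")  # Hamming on binary maps
        tree = linkage(condensed, method="average")
        labels = fcluster(tree, t=max_clusters, criterion="maxclust") - 1

    labels = _merge_small(labels, mat, min_occupancy)
    unique = np.unique(labels)
    relabel = {u: k for k, u in enumerate(unique)}
    labels = np.array([relabel[u] for u in labels])

    sizes = np.bincount(labels)
    prob_maps = []
    reps = []
    for c in range(len(sizes)):
        members = np.nonzero(labels == c)[0]
        sub = mat[members]
        freq = sub.mean(axis=0)
        prob_maps.append(
            {pairs[k]: float(freq[k]) for k in range(len(pairs)) if freq[k] > 0}
        )
        dists = (sub[:, None, :] != sub[None, :, :]).sum(axis=(1, 2))
        reps.append(int(members[np.argmin(dists)]))  # argmin: lowest index on ties
    return ClusterSet(
        assignments=labels,
        sizes=sizes,
        occupancies=sizes / m,
        probability_maps=prob_maps,
        representatives=reps,
    )


def _merge_small(labels: np.ndarray, mat: np.ndarray, min_occupancy: float) -> np.ndarray:
    labels = labels.copy()
    m = len(labels)
    while True:
        sizes = pd.Series(labels).value_counts()
        small = [c for c, s in sizes.items() if s / m < min_occupancy]
        if not small or len(sizes) <= 1:
            return labels
        c = min(small, key=lambda c: sizes[c])
        members = labels == c
        best, best_d = None, np.inf
        for other in sizes.index:
            if other == c:
                continue
            om = labels == other
            d = (mat[members][:, None, :] != mat[om][None, :, :]).sum(axis=2).mean()
            if d < best_d:
                best, best_d = other, d
        labels[members] = best


def nonnative_profile(
    results: Sequence[FoldingResult], native: NativeStructure
) -> pd.DataFrame:
    """Mean non-native contact count per Q over all recorded snapshots."""
    n_native = len(native.native_map)
    nat = np.concatenate(
        [r.snapshot_nat for r in results if r.snapshot_nat is not None]
    )
    tot = np.concatenate(
        [r.snapshot_tot for r in results if r.snapshot_tot is not None]
    )
    nonnat = tot - nat
    df = pd.DataFrame({"Q": nat / n_native, "n_nonnative": nonnat})
    grouped = df.groupby("Q")["n_nonnative"]
    out = grouped.agg(["mean", "count", "std"]).reset_index()
    out["stderr"] = out["std"] / np.sqrt(out["count"])
    return out.rename(columns={"mean": "mean_nonnative", "count": "n"})[
        ["Q", "n", "mean_nonnative", "stderr"]
    ]
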