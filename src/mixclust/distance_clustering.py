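"""Distance/dissimilarity-based partitioning.

* **PAM** (partitioning around medoids): BUILD then SWAP, minimising the
  total deviation TD = sum of dissimilarities of each observation to its
  cluster's medoid.
* **Ward ascendant hierarchical clustering**: Lance-Williams agglomeration
  with the size-weighted Ward coefficients, applied by default on squared
  dissimilarities (the ward.D2 convention); a raw-d variant is exposed.
* **K-prototypes**: k-means-style alternation on mixed data with the
  distance d2 = squared Euclidean (continuous) + gamma * Hamming
  (categorical), minimising the total sum of distances to prototypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MixedDataset, Partition
from .dissimilarity import DissimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PAMState",
    "KPrototypesState",
    "pam",
    "hac_ward",
    "ward_heights",
    "kprototypes",
    "estimate_gamma",
]


@dataclass
class PAMState:
    medoids: np.ndarray  # sorted observation indices, one per cluster
    total_deviation: float


@dataclass
class KPrototypesState:
    prototypes_continuous: np.ndarray  # (G, q) per-cluster means
    prototypes_categorical: np.ndarray  # (G, p-q) per-cluster modes
    gamma: float
    total_sum_distances: float


def _as_matrix(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def _assign_to_medoids(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # argmin breaks ties toward the lowest medoid position; medoids kept sorted
    return np.argmin(D[:, medoids], axis=1)


def pam(
    D: DissimilarityMatrix | np.ndarray, n_clusters: int
) -> tuple[Partition, PAMState]:
    """Partitioning around medoids with the classical BUILD + SWAP phases.

    BUILD seeds the first medoid as the observation with the smallest total
    dissimilarity to all others, then adds medoids greedily by maximal TD
    reduction.  SWAP repeatedly applies the single (medoid, non-medoid)
    exchange that most reduces TD until no improving exchange exists.
    Ties are broken toward the lowest observation index.
    """
    d = _as_matrix(D)
    n = d.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in 1..{n}")
    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    dnear = d[:, medoids[0]].copy()
    while len(medoids) < n_clusters:
        candidates = np.setdiff1d(np.arange(n), medoids)
        reductions = np.maximum(dnear[:, None] - d[:, candidates], 0.0).sum(axis=0)
        best = int(candidates[np.argmax(reductions)])
        medoids.append(best)
        dnear = np.minimum(dnear, d[:, best])
    medoids = np.array(sorted(medoids))
    # SWAP
    while True:
        dm = d[:, medoids]  # (n, G)
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = dm[np.arange(n), nearest]
        d2 = dm[np.arange(n), order[:, 1]] if n_clusters > 1 else np.full(n, np.inf)
        td = d1.sum()
        others = np.setdiff1d(np.arange(n), medoids)
        if others.size == 0:
            break
        best_td, best_swap = td, None
        for pos in range(n_clusters):
            # removing medoid `pos`: points whose nearest it was fall back to d2
            base = np.where(nearest == pos, d2, d1)
            new_tds = np.minimum(d[:, others], base[:, None]).sum(axis=0)
            k = int(np.argmin(new_tds))
            if new_tds[k] < best_td - 1e-12:
                best_td, best_swap = new_tds[k], (pos, int(others[k]))
        if best_swap is None:
            break
        pos, h = best_swap
        medoids[pos] = h
        medoids = np.sort(medoids)
    labels = _assign_to_medoids(d, medoids)
    td = float(d[np.arange(n), medoids[labels]].sum())
    return Partition(labels=labels, n_clusters=n_clusters), PAMState(
        medoids=medoids, total_deviation=td
    )


def _ward_merges(w: np.ndarray, n_merges: int):
    """Lance-Williams Ward agglomeration on the working matrix ``w`` (in place).

    Yields (i, j, height2) per merge, where i absorbs j and height2 is the
    working-scale distance at fusion.  Ties merge the lexicographically
    smallest pair.
    """
    n = w.shape[0]
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    work = w.copy()
    np.fill_diagonal(work, np.inf)
    for _ in range(n_merges):
        flat = int(np.argmin(work))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h2 = work[i, j]
        ni, nj, nk = sizes[i], sizes[j], sizes
        mask = active.copy()
        mask[[i, j]] = False
        denom = ni + nj + nk[mask]
        new = (
            (ni + nk[mask]) * work[i, mask]
            + (nj + nk[mask]) * work[j, mask]
            - nk[mask] * h2
        ) / denom
        work[i, mask] = new
        work[mask, i] = new
        work[j, :] = np.inf
        work[:, j] = np.inf
        sizes[i] = ni + nj
        active[j] = False
        yield i, j, h2


def hac_ward(
    D: DissimilarityMatrix | np.ndarray, n_clusters: int, squared: bool = True
) -> Partition:
    """Agglomerate from singletons under the Ward criterion and cut at G.

    d(Ci u Cj, Ck) = [(ni+nk) d(Ci,Ck) + (nj+nk) d(Cj,Ck) - nk d(Ci,Cj)]
                     / (ni+nj+nk)

    With ``squared=True`` (default) the update runs on squared
    dissimilarities and fusion heights are square-rooted back — the ward.D2
    convention of the software the benchmark mirrors.  ``squared=False``
    applies the update to the raw dissimilarities.
    """
    d = _as_matrix(D)
    n = d.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in 1..{n}")
    w = d**2 if squared else d.copy()
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, j, _ in _ward_merges(w, n - n_clusters):
        members[i].extend(members.pop(j))
    labels = np.empty(n, dtype=np.int64)
    for g, (_, obs) in enumerate(sorted(members.items())):
        labels[obs] = g
    return Partition(labels=labels, n_clusters=n_clusters)


def ward_heights(
    D: DissimilarityMatrix | np.ndarray, squared: bool = True
) -> np.ndarray:
    """Fusion heights of the full Ward dendrogram (length N-1)."""
    d = _as_matrix(D)
    n = d.shape[0]
    w = d**2 if squared else d.copy()
    h2 = np.array([h for _, _, h in _ward_merges(w, n - 1)])
    return np.sqrt(np.maximum(h2, 0.0)) if squared else h2


def estimate_gamma(ds: MixedDataset) -> float:
    """Categorical weight from the combined variance of the data.

    Mean sample variance of the continuous columns divided by the mean of
    1 - sum_l f_l^2 (the Gini impurity, a categorical variance analogue)
    over categorical columns.
    """
    if ds.n_continuous == 0 or ds.n_categorical == 0:
        return 1.0
    num = float(np.mean(ds.continuous.var(axis=0, ddof=1)))
    impurities = []
    for j in range(ds.n_categorical):
        freqs = np.bincount(ds.categorical[:, j], minlength=ds.level_counts[j]) / ds.n_obs
        impurities.append(1.0 - np.sum(freqs**2))
    den = float(np.mean(impurities))
    if den <= 0.0:
        logger.warning("all categorical columns constant; gamma fixed to 1")
        return 1.0
    return num / den


def _d2_matrix(
    ds: MixedDataset, proto_cont: np.ndarray, proto_cat: np.ndarray, gamma: float
) -> np.ndarray:
    """d2(x, b_g) for every observation x and prototype b_g, shape (N, G)."""
    d = np.zeros((ds.n_obs, proto_cont.shape[0]))
    if ds.n_continuous:
        diff = ds.continuous[:, None, :] - proto_cont[None, :, :]
        d += np.einsum("ngj,ngj->ng", diff, diff)
    if ds.n_categorical:
        d += gamma * (ds.categorical[:, None, :] != proto_cat[None, :, :]).sum(axis=2)
    return d


def kprototypes(
    ds: MixedDataset,
    n_clusters: int,
    gamma: float | None = None,
    n_init: int = 10,
    max_iter: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[Partition, KPrototypesState]:
    """K-prototypes: Lloyd-style alternation on the mixed distance d2.

    Prototypes hold per-cluster continuous means and categorical modes; the
    categorical weight gamma defaults to :func:`estimate_gamma`.  The best
    of ``n_init`` random starts (G distinct observations as initial
    prototypes) by total sum of distances is returned.
    """
    if rng is None:
        rng = np.random.default_rng()
    n, G = ds.n_obs, n_clusters
    if not 1 <= G <= n:
        raise ValueError(f"n_clusters must lie in 1..{n}")
    if gamma is None:
        gamma = estimate_gamma(ds)
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        seed_idx = rng.choice(n, size=G, replace=False)
        proto_cont = ds.continuous[seed_idx].copy()
        proto_cat = ds.categorical[seed_idx].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            dist = _d2_matrix(ds, proto_cont, proto_cat, gamma)
            new_labels = np.argmin(dist, axis=1)
            # re-seed emptied clusters at the observation farthest from its prototype
            for g in range(G):
                if not np.any(new_labels == g):
                    far = int(np.argmax(dist[np.arange(n), new_labels]))
                    logger.info("k-prototypes: re-seeding emptied cluster %d at obs %d", g, far)
                    new_labels[far] = g
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for g in range(G):
                rows = labels == g
                if ds.n_continuous:
                    proto_cont[g] = ds.continuous[rows].mean(axis=0)
                for j in range(ds.n_categorical):
                    counts = np.bincount(
                        ds.categorical[rows, j], minlength=ds.level_counts[j]
                    )
                    proto_cat[g, j] = int(np.argmax(counts))  # ties -> lowest level code
        dist = _d2_matrix(ds, proto_cont, proto_cat, gamma)
        tsd = float(dist[np.arange(n), labels].sum())
        if best is None or tsd < best[0]:
            best = (tsd, labels.copy(), proto_cont.copy(), proto_cat.copy())
    tsd, labels, proto_cont, proto_cat = best
    return Partition(labels=labels, n_clusters=G), KPrototypesState(
        prototypes_continuous=proto_cont,
        prototypes_categorical=proto_cat,
        gamma=float(gamma),
        total_sum_distances=tsd,
    )
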