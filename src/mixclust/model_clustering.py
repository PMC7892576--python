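"""Model-based clustering of mixed data.

All four methods assume within-cluster independence across variables:

* **em_mixture** — finite mixture with diagonal-covariance Gaussian
  components on the continuous block and multinomial components on the
  categorical block, fitted by EM; a soft (standard) and a hard
  (classification-EM, maximising the completed log-likelihood L_c) variant
  are both provided, plus presets mirroring the benchmarked software
  defaults ("mixmod": one run, 200 iterations; "lcm": multi-start
  small-EM followed by a tolerance-driven run).
* **kamila** — semiparametric alternation: spherical-cluster continuous
  part handled through a kernel density estimate of the minimal
  point-to-centroid Euclidean distances (radially corrected for the
  dimension), categorical part through multinomial log-probabilities.
* **lca** — multinomial mixture on categorical-only data; continuous
  variables enter after tertile discretisation (:func:`discretize_tertiles`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .core import MixedDataset, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureFit",
    "KamilaFit",
    "em_mixture",
    "mixmod_cluster",
    "lcm_cluster",
    "kamila",
    "discretize_tertiles",
    "lca",
    "lca_pipeline",
]

#: Laplace smoothing applied to every multinomial estimate so log-densities
#: stay finite
EPS_MULTINOMIAL = 1e-10


@dataclass
class MixtureFit:
    """Fitted normal/multinomial mixture parameters and diagnostics."""

    tau: np.ndarray  # (G,) mixing proportions
    means: np.ndarray  # (G, q)
    variances: np.ndarray  # (G, q) diagonal variances
    cat_probs: list[np.ndarray]  # per categorical variable: (G, L_j)
    responsibilities: np.ndarray  # (N, G) row-stochastic t_ig
    loglik_trace: list[float] = field(default_factory=list)
    completed_loglik: float | None = None
    converged: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


@dataclass
class KamilaFit:
    centroids: np.ndarray  # (G, q)
    cat_probs: list[np.ndarray]  # per categorical variable: (G, L_j)
    objective: float
    n_runs: int
    min_distances: np.ndarray  # the N minimal distances of the final iteration


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


class _CatDesign:
    """Stacked one-hot design of the categorical block (one matmul per EM step)."""

    def __init__(self, ds: MixedDataset) -> None:
        blocks = [_one_hot(ds.categorical[:, j], int(L)) for j, L in enumerate(ds.level_counts)]
        self.matrix = np.hstack(blocks) if blocks else np.empty((ds.n_obs, 0))
        bounds = np.concatenate([[0], np.cumsum(ds.level_counts)]).astype(int)
        self.slices = [slice(bounds[j], bounds[j + 1]) for j in range(len(ds.level_counts))]

    def logdensity(self, cat_probs: list[np.ndarray]) -> np.ndarray:
        if not cat_probs:
            return 0.0
        stacked = np.log(np.vstack([p.T for p in cat_probs]))  # (sum L, G)
        return self.matrix @ stacked

    def level_counts_per_cluster(self, weights: np.ndarray) -> np.ndarray:
        return weights.T @ self.matrix  # (G, sum L)


def _component_logdensity(
    ds: MixedDataset,
    means: np.ndarray,
    variances: np.ndarray,
    cat_probs: list[np.ndarray],
    design: "_CatDesign",
) -> np.ndarray:
    """log h(x_i | alpha_g): (N, G) product of univariate normals and pmfs."""
    n = ds.n_obs
    G = means.shape[0] if means.size else cat_probs[0].shape[0]
    logh = np.zeros((n, G))
    if ds.n_continuous:
        # sum_j log N(x_ij; mu_gj, sigma2_gj), vectorised over clusters
        x = ds.continuous[:, None, :]
        logh += (
            -0.5 * np.log(2.0 * np.pi * variances)[None, :, :]
            - 0.5 * (x - means[None, :, :]) ** 2 / variances[None, :, :]
        ).sum(axis=2)
    if ds.n_categorical:
        logh += design.logdensity(cat_probs)
    return logh


def _m_step(
    ds: MixedDataset,
    weights: np.ndarray,
    var_floor: np.ndarray,
    design: "_CatDesign",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    """Closed-form weighted MLE for tau, means, variances and level probs."""
    n, G = weights.shape
    ng = weights.sum(axis=0)
    ng = np.maximum(ng, 1e-12)
    tau = ng / n
    if ds.n_continuous:
        means = (weights.T @ ds.continuous) / ng[:, None]
        sq = (weights.T @ ds.continuous**2) / ng[:, None]
        variances = np.maximum(sq - means**2, var_floor[None, :])
    else:
        means = np.empty((G, 0))
        variances = np.empty((G, 0))
    cat_probs = []
    if ds.n_categorical:
        all_counts = design.level_counts_per_cluster(weights)
        for sl in design.slices:
            probs = all_counts[:, sl] + EPS_MULTINOMIAL
            probs /= probs.sum(axis=1, keepdims=True)
            cat_probs.append(probs)
    return tau, means, variances, cat_probs


def _init_params(
    ds: MixedDataset,
    G: int,
    rng: np.random.Generator,
    var_floor: np.ndarray,
    style: str,
    design: "_CatDesign",
):
    if style == "random_responsibilities":
        # diffuse start; prone to symmetric ridges, kept for comparison
        weights = rng.dirichlet(np.ones(G), size=ds.n_obs)
        return _m_step(ds, weights, var_floor, design)
    if style == "uniform_tau_random_alpha":
        # uniform mixing proportions, component centres drawn from the data,
        # level probabilities randomly sampled (the usual random start of
        # mixture software; diffuse-responsibility starts collapse all
        # components onto the global statistics)
        tau = np.full(G, 1.0 / G)
        if ds.n_continuous:
            idx = rng.choice(ds.n_obs, size=G, replace=False)
            means = ds.continuous[idx]
            variances = np.tile(ds.continuous.var(axis=0) + var_floor, (G, 1))
        else:
            means = np.empty((G, 0))
            variances = np.empty((G, 0))
        cat_probs = [
            rng.dirichlet(np.ones(int(L)), size=G) + EPS_MULTINOMIAL
            for L in ds.level_counts
        ]
        cat_probs = [p / p.sum(axis=1, keepdims=True) for p in cat_probs]
        return tau, means, variances, cat_probs
    raise ValueError(f"unknown init style {style!r}")


def _fit_em_once(
    ds: MixedDataset,
    G: int,
    mode: str,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
    init_style: str,
    params=None,
) -> MixtureFit:
    n = ds.n_obs
    var_floor = (
        1e-6 * np.maximum(ds.continuous.var(axis=0), 1e-12)
        if ds.n_continuous
        else np.empty(0)
    )
    design = _CatDesign(ds)
    if params is None:
        tau, means, variances, cat_probs = _init_params(
            ds, G, rng, var_floor, init_style, design
        )
    else:
        tau, means, variances, cat_probs = params
    trace: list[float] = []
    t = np.full((n, G), 1.0 / G)
    converged = False
    completed = None
    for _ in range(max_iter):
        logh = _component_logdensity(ds, means, variances, cat_probs, design)
        logw = np.log(tau)[None, :] + logh
        lse = logsumexp(logw, axis=1)
        t = np.exp(logw - lse[:, None])
        if mode == "soft":
            objective = float(lse.sum())
            weights = t
        else:  # hard: classification EM on the completed log-likelihood L_c
            z = np.argmax(t, axis=1)
            empty = [g for g in range(G) if not np.any(z == g)]
            if empty:
                # re-seed emptied clusters from the least-committed points
                order = np.argsort(np.max(t, axis=1), kind="stable")
                for g, worst in zip(empty, order):
                    logger.info("hard EM: re-seeding empty cluster %d at obs %d", g, int(worst))
                    z[worst] = g
            objective = float(logw[np.arange(n), z].sum())
            weights = np.zeros((n, G))
            weights[np.arange(n), z] = 1.0
            completed = objective
        trace.append(objective)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        tau, means, variances, cat_probs = _m_step(ds, weights, var_floor, design)
        tau = np.maximum(tau, 1e-12)
        tau /= tau.sum()
    return MixtureFit(
        tau=tau,
        means=means,
        variances=variances,
        cat_probs=cat_probs,
        responsibilities=t,
        loglik_trace=trace,
        completed_loglik=completed,
        converged=converged,
    )


def em_mixture(
    ds: MixedDataset,
    n_clusters: int,
    mode: str = "soft",
    n_init: int = 1,
    max_iter: int = 200,
    tol: float = 1e-8,
    rng: np.random.Generator | None = None,
    small_em_iters: int | None = None,
    init_style: str = "uniform_tau_random_alpha",
) -> tuple[Partition, MixtureFit]:
    """EM for the diagonal normal / multinomial mixture on mixed data.

    ``mode='soft'`` maximises the observed-data log-likelihood (monotone by
    the EM ascent property); ``mode='hard'`` assigns by argmax t_ig each
    step and maximises the completed log-likelihood L_c.  With
    ``small_em_iters`` set and several starts, every start runs only that
    many iterations, and the best interim fit is refined to convergence.
    """
    if rng is None:
        rng = np.random.default_rng()
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    if n_clusters < 1 or n_clusters > ds.n_obs:
        raise ValueError("invalid number of clusters")
    if ds.n_variables == 0:
        raise ValueError("dataset has no variables")
    best: MixtureFit | None = None
    short = small_em_iters if (small_em_iters and n_init > 1) else max_iter
    for _ in range(n_init):
        fit = _fit_em_once(ds, n_clusters, mode, short, tol, rng, init_style)
        if best is None or fit.loglik > best.loglik:
            best = fit
    if short < max_iter:
        params = (best.tau, best.means, best.variances, best.cat_probs)
        best = _fit_em_once(
            ds, n_clusters, mode, max_iter, tol, rng, init_style, params=params
        )
    labels = np.argmax(best.responsibilities, axis=1)
    return Partition(labels=labels, n_clusters=n_clusters), best


def mixmod_cluster(
    ds: MixedDataset,
    n_clusters: int,
    rng: np.random.Generator | None = None,
    mode: str = "soft",
) -> tuple[Partition, MixtureFit]:
    """Mixture-modelling preset: a single run of at most 200 EM iterations,
    least-constrained diagonal model (free proportions, means, variances and
    level probabilities per cluster)."""
    return em_mixture(ds, n_clusters, mode=mode, n_init=1, max_iter=200, tol=1e-8, rng=rng)


def lcm_cluster(
    ds: MixedDataset,
    n_clusters: int,
    rng: np.random.Generator | None = None,
    n_init: int = 20,
) -> tuple[Partition, MixtureFit]:
    """Latent-class-model preset: soft EM with multi-start small EM
    (20 starts by default) and a tolerance-driven final run.  Variable and
    cluster-count selection are deliberately disabled: every variable is
    treated as relevant and G is supplied by the caller."""
    return em_mixture(
        ds,
        n_clusters,
        mode="soft",
        n_init=n_init,
        max_iter=500,
        tol=1e-8,
        rng=rng,
        small_em_iters=10,
    )


def _log_sphere_surface(q: int) -> float:
    """log surface area of the unit (q-1)-sphere in R^q."""
    return math.log(2.0) + (q / 2.0) * math.log(math.pi) - gammaln(q / 2.0)


def _radial_logdensity(distances: np.ndarray, min_dist: np.ndarray, q: int) -> np.ndarray:
    """log f_V at ``distances`` from a KDE of the minimal distances.

    The kernel density estimate of the N minimal distances (Silverman
    bandwidth) describes the radius distribution; dividing by the surface
    area S_{q-1} r^{q-1} of the radius-r sphere converts it into the value
    of the underlying spherical density at that distance.
    """
    spread = min_dist.std()
    if spread < 1e-12:
        # all minimal distances identical: degenerate KDE; flat radius density
        kde_vals = np.full(distances.shape, 1.0)
    else:
        kde = stats.gaussian_kde(min_dist, bw_method="silverman")
        kde_vals = kde(distances.ravel()).reshape(distances.shape)
    r = np.maximum(distances, 1e-9)
    return (
        np.log(np.maximum(kde_vals, 1e-300))
        - _log_sphere_surface(q)
        - (q - 1) * np.log(r)
    )


def kamila(
    ds: MixedDataset,
    n_clusters: int,
    n_runs: int = 10,
    max_iter: int = 25,
    rng: np.random.Generator | None = None,
) -> tuple[Partition, KamilaFit]:
    """Semiparametric k-means/EM hybrid for mixed data.

    Each iteration (a) computes Euclidean distances of every observation to
    every centroid, (b) estimates the density of the N minimal distances by
    a radially corrected KDE, (c) assigns each observation to the cluster
    maximising log f(dist) + sum_j log p(x_j | cluster), and (d) refreshes
    centroids (cluster means) and categorical level probabilities
    (Laplace-smoothed frequencies).  The best of ``n_runs`` random starts by
    final combined log-likelihood is returned.
    """
    if rng is None:
        rng = np.random.default_rng()
    if ds.n_continuous == 0:
        # degenerate input: no distances to model, fall back to the
        # multinomial mixture EM
        logger.warning("kamila needs continuous variables; falling back to em_mixture")
        return em_mixture(ds, n_clusters, n_init=n_runs, rng=rng)
    if ds.n_categorical == 0:
        logger.warning("kamila without categorical variables degenerates; proceeding")
    n, G, q = ds.n_obs, n_clusters, ds.n_continuous
    if not 1 <= G <= n:
        raise ValueError("invalid number of clusters")
    best: tuple[float, np.ndarray, np.ndarray, list[np.ndarray], np.ndarray] | None = None
    for _ in range(n_runs):
        centroids = ds.continuous[rng.choice(n, size=G, replace=False)].copy()
        cat_probs = [
            np.full((G, int(L)), 1.0 / int(L)) for L in ds.level_counts
        ]
        labels = np.full(n, -1)
        objective = -np.inf
        for _ in range(max_iter):
            diff = ds.continuous[:, None, :] - centroids[None, :, :]
            dist = np.sqrt(np.einsum("ngj,ngj->ng", diff, diff))
            min_dist = dist.min(axis=1)
            logscore = _radial_logdensity(dist, min_dist, q)
            for j in range(ds.n_categorical):
                logscore += np.log(cat_probs[j])[:, ds.categorical[:, j]].T
            new_labels = np.argmax(logscore, axis=1)
            point_fit = logscore[np.arange(n), new_labels]
            for g in range(G):
                if not np.any(new_labels == g):
                    worst = int(np.argmin(point_fit))
                    logger.info("kamila: re-seeding empty cluster %d at obs %d", g, worst)
                    new_labels[worst] = g
                    centroids[g] = ds.continuous[worst]
            objective = float(logscore[np.arange(n), new_labels].sum())
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for g in range(G):
                rows = labels == g
                centroids[g] = ds.continuous[rows].mean(axis=0)
            for j in range(ds.n_categorical):
                L = int(ds.level_counts[j])
                counts = np.zeros((G, L))
                for level in range(L):
                    counts[:, level] = np.bincount(
                        labels[ds.categorical[:, j] == level], minlength=G
                    )
                probs = counts + EPS_MULTINOMIAL
                cat_probs[j] = probs / probs.sum(axis=1, keepdims=True)
        if best is None or objective > best[0]:
            best = (objective, labels.copy(), centroids.copy(), [p.copy() for p in cat_probs], min_dist.copy())
    objective, labels, centroids, cat_probs, min_dist = best
    return Partition(labels=labels, n_clusters=G), KamilaFit(
        centroids=centroids,
        cat_probs=cat_probs,
        objective=objective,
        n_runs=n_runs,
        min_distances=min_dist,
    )


def discretize_tertiles(column: np.ndarray) -> np.ndarray:
    """Cut a continuous column into three balanced classes at the empirical
    1/3 and 2/3 quantiles; falls back to rank-based splitting when ties
    empty a class."""
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D column")
    if np.ptp(x) == 0.0:
        raise ValueError("cannot discretize a constant column")
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    codes = (x > q1).astype(np.int64) + (x > q2).astype(np.int64)
    if np.unique(codes).size < 3:
        logger.warning("tertile cut degenerate under ties; using rank-based split")
        ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
        codes = (3 * ranks // x.size).astype(np.int64)
    return codes


def lca(
    cat_ds: MixedDataset,
    n_clusters: int,
    n_runs: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-10,
    rng: np.random.Generator | None = None,
) -> tuple[Partition, MixtureFit]:
    """Latent class analysis: EM on a mixture of multinomials.

    Only categorical variables are allowed (continuous columns must be
    discretised first).  Each run starts from uniform mixing proportions and
    randomly sampled level probabilities, and stops when two successive
    log-likelihoods differ by less than ``tol`` (1e-10 by default); the run
    with the best final log-likelihood wins.
    """
    if cat_ds.n_continuous != 0:
        raise ValueError("lca accepts categorical variables only; discretize first")
    if rng is None:
        rng = np.random.default_rng()
    best: MixtureFit | None = None
    for _ in range(n_runs):
        fit = _fit_em_once(
            cat_ds,
            n_clusters,
            "soft",
            max_iter,
            tol,
            rng,
            "uniform_tau_random_alpha",
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    labels = np.argmax(best.responsibilities, axis=1)
    return Partition(labels=labels, n_clusters=n_clusters), best


def lca_pipeline(
    ds: MixedDataset,
    n_clusters: int,
    n_runs: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-10,
    rng: np.random.Generator | None = None,
) -> tuple[Partition, MixtureFit]:
    """End-to-end LCA on mixed data: tertile-discretise every continuous
    column, append the raw categorical columns, and run :func:`lca`."""
    cols = [discretize_tertiles(ds.continuous[:, j]) for j in range(ds.n_continuous)]
    categorical = (
        np.column_stack(cols + [ds.categorical[:, j] for j in range(ds.n_categorical)])
        if cols or ds.n_categorical
        else np.empty((ds.n_obs, 0), dtype=np.int64)
    )
    level_counts = np.concatenate(
        [np.full(len(cols), 3, dtype=np.int64), ds.level_counts]
    )
    cat_only = MixedDataset(
        continuous=np.empty((ds.n_obs, 0)),
        categorical=categorical,
        level_counts=level_counts,
        true_labels=ds.true_labels,
    )
    return lca(cat_only, n_clusters, n_runs=n_runs, max_iter=max_iter, tol=tol, rng=rng)
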