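"""Synthetic mixed-data generator with controlled cluster structure.

Continuous variables are drawn from spherical unit-variance Gaussian
clusters whose centres sit on a randomly oriented line, spaced so that each
cluster attains a target quantile-based *separation index* with its nearest
neighbour (negative = overlapping, positive = gapped, bounded in ]-2, +2[).
Categorical variables carry one level per true cluster, degraded by
resampling a controlled fraction of values uniformly over the levels.
Fully irrelevant padding variables of either type can be appended, and the
continuous block can be standardised exactly as the benchmark feeds it to
the clustering methods.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .core import MixedDataset, ScenarioSpec, VariableMeta

__all__ = [
    "separation_distance",
    "estimate_separation_index",
    "generate_continuous",
    "generate_categorical",
    "add_irrelevant_variables",
    "scale_continuous",
    "generate_scenario",
]


def separation_distance(sep_index: float, alpha: float = 0.05) -> float:
    """Centre spacing delta achieving separation index J for two unit-variance
    spherical Gaussian clusters.

    For N(0,1) and N(delta,1) projected on the centre line, the alpha-quantile
    separation index is (delta - 2z)/(delta + 2z) with z the (1 - alpha/2)
    normal quantile; solving for delta gives ``2 z (1 + J) / (1 - J)``.
    """
    if not -2.0 < sep_index < 2.0:
        raise ValueError(f"separation index must lie in ]-2, +2[, got {sep_index}")
    if sep_index >= 1.0:
        raise ValueError("indices >= 1 are unreachable for Gaussian clusters at finite spacing")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return 2.0 * z * (1.0 + sep_index) / (1.0 - sep_index)


def estimate_separation_index(
    sample_a: np.ndarray, sample_b: np.ndarray, alpha: float = 0.05
) -> float:
    """Empirical separation index of two 1-D projected samples.

    With L_k / U_k the alpha/2 and 1-alpha/2 empirical quantiles of the two
    samples (ordered so the second has the larger centre), the index is
    ``(L2 - U1) / (U2 - L1)``: negative when the central mass overlaps,
    positive when a gap separates it.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if a.mean() > b.mean():
        a, b = b, a
    lo_a, hi_a = np.quantile(a, [alpha / 2.0, 1.0 - alpha / 2.0])
    lo_b, hi_b = np.quantile(b, [alpha / 2.0, 1.0 - alpha / 2.0])
    denom = hi_b - lo_a
    if denom <= 0.0:
        raise ValueError("separation index undefined: both samples have zero spread")
    return float((lo_b - hi_a) / denom)


def balanced_sizes(n_obs: int, n_clusters: int) -> np.ndarray:
    """Cluster sizes floor(N/G) or ceil(N/G), remainder to the lowest indices."""
    base, rem = divmod(n_obs, n_clusters)
    sizes = np.full(n_clusters, base, dtype=np.int64)
    sizes[:rem] += 1
    return sizes


def generate_continuous(
    n_obs: int,
    n_clusters: int,
    n_vars: int,
    sep_index: float,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample balanced spherical Gaussian clusters at a target separation.

    Centres are placed on a randomly oriented line through the origin at the
    spacing :func:`separation_distance` prescribes, so each cluster's nearest
    neighbour attains the target index in expectation.

    Returns the (N, n_vars) matrix and the true labels (0..G-1).
    """
    if n_vars < 1:
        raise ValueError("at least one continuous variable is required")
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    if n_obs < n_clusters:
        raise ValueError(f"cannot place {n_clusters} non-empty clusters in {n_obs} observations")
    delta = separation_distance(sep_index, alpha=alpha)
    direction = rng.standard_normal(n_vars)
    direction /= np.linalg.norm(direction)
    # centres k*delta*u, recentred so the configuration has zero mean
    offsets = (np.arange(n_clusters) - (n_clusters - 1) / 2.0) * delta
    centres = offsets[:, None] * direction[None, :]
    sizes = balanced_sizes(n_obs, n_clusters)
    labels = np.repeat(np.arange(n_clusters), sizes)
    data = rng.standard_normal((n_obs, n_vars)) + centres[labels]
    return data, labels


def generate_categorical(
    true_labels: np.ndarray,
    n_clusters: int,
    noise_prop: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One categorical variable with G levels aligned to the true clusters.

    Each row starts at level = its cluster index; exactly
    ``round(noise_prop * N)`` rows (chosen without replacement) are then
    resampled uniformly over all G levels, including the current one.
    """
    labels = np.asarray(true_labels, dtype=np.int64)
    if not 0.0 <= noise_prop <= 1.0:
        raise ValueError("noise_prop must lie in [0, 1]")
    if labels.min() < 0 or labels.max() >= n_clusters:
        raise ValueError("labels out of range 0..G-1")
    values = labels.copy()
    n_noisy = int(round(noise_prop * labels.size))
    if n_noisy:
        idx = rng.choice(labels.size, size=n_noisy, replace=False)
        values[idx] = rng.integers(0, n_clusters, size=n_noisy)
    return values


def add_irrelevant_variables(
    ds: MixedDataset,
    n_cont: int,
    n_cat: int,
    rng: np.random.Generator,
) -> MixedDataset:
    """Append label-independent padding variables.

    Continuous padding is standard normal; categorical padding is uniform
    over G levels.  Relevance metadata marks the new columns irrelevant.
    """
    if ds.true_labels is None:
        raise ValueError("dataset must carry true labels")
    if n_cont == 0 and n_cat == 0:
        return ds
    n_obs, n_clusters = ds.n_obs, ds.n_clusters
    continuous = ds.continuous
    cont_meta = list(ds.continuous_meta)
    if n_cont:
        noise = rng.standard_normal((n_obs, n_cont))
        continuous = np.hstack([ds.continuous, noise]) if ds.n_continuous else noise
        cont_meta += [
            VariableMeta(f"num{ds.n_continuous + j + 1}", relevant=False)
            for j in range(n_cont)
        ]
    categorical = ds.categorical
    level_counts = ds.level_counts
    cat_meta = list(ds.categorical_meta)
    if n_cat:
        noise = rng.integers(0, n_clusters, size=(n_obs, n_cat))
        categorical = np.hstack([ds.categorical, noise]) if ds.n_categorical else noise
        level_counts = np.concatenate([ds.level_counts, np.full(n_cat, n_clusters)])
        cat_meta += [
            VariableMeta(f"cat{ds.n_categorical + j + 1}", relevant=False)
            for j in range(n_cat)
        ]
    return MixedDataset(
        continuous=continuous,
        categorical=categorical,
        level_counts=level_counts,
        true_labels=ds.true_labels,
        continuous_meta=cont_meta,
        categorical_meta=cat_meta,
    )


def scale_continuous(ds: MixedDataset) -> MixedDataset:
    """Standardise each continuous column to mean 0, sample sd 1 (ddof=1)."""
    if ds.n_continuous == 0:
        return ds
    sd = ds.continuous.std(axis=0, ddof=1) if ds.n_obs > 1 else np.zeros(ds.n_continuous)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = [ds.continuous_meta[j].name for j in bad]
        raise ValueError(f"cannot scale constant continuous column(s): {names}")
    out = ds.copy()
    out.continuous = (ds.continuous - ds.continuous.mean(axis=0)) / sd
    return out


def generate_scenario(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    scale: bool = True,
    alpha: float = 0.05,
) -> MixedDataset:
    """Generate one labelled dataset under a scenario specification.

    Relevant continuous variables are drawn jointly at the degree's target
    separation index; relevant categorical variables each carry the degree's
    noise proportion; irrelevant padding of both types is appended; finally
    the continuous block is standardised (all methods consume the same
    scaled table).
    """
    n_rel_cont = spec.n_relevant("continuous")
    n_rel_cat = spec.n_relevant("categorical")
    if spec.n_continuous > 0 and n_rel_cont == 0:
        raise ValueError("at least one relevant continuous variable is required")
    if n_rel_cont > 0:
        continuous, labels = generate_continuous(
            spec.population_size,
            spec.n_clusters,
            n_rel_cont,
            spec.sep_index,
            rng,
            alpha=alpha,
        )
        cont_meta = [
            VariableMeta(f"num{j + 1}", relevant=True, degree=spec.degree_continuous)
            for j in range(n_rel_cont)
        ]
    else:
        continuous = np.empty((spec.population_size, 0))
        sizes = balanced_sizes(spec.population_size, spec.n_clusters)
        labels = np.repeat(np.arange(spec.n_clusters), sizes)
        cont_meta = []
    categorical = np.column_stack(
        [
            generate_categorical(labels, spec.n_clusters, spec.noise_prop, rng)
            for _ in range(n_rel_cat)
        ]
    ) if n_rel_cat else np.empty((spec.population_size, 0), dtype=np.int64)
    cat_meta = [
        VariableMeta(f"cat{j + 1}", relevant=True, degree=spec.degree_categorical)
        for j in range(n_rel_cat)
    ]
    ds = MixedDataset(
        continuous=continuous,
        categorical=categorical,
        level_counts=np.full(n_rel_cat, spec.n_clusters, dtype=np.int64),
        true_labels=labels,
        continuous_meta=cont_meta,
        categorical_meta=cat_meta,
    )
    ds = add_irrelevant_variables(
        ds, spec.n_continuous - n_rel_cont, spec.n_categorical - n_rel_cat, rng
    )
    if scale:
        ds = scale_continuous(ds)
    return ds


def nearest_pair_separation(
    data: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> float:
    """Empirical separation index of the closest pair of clusters.

    Each cluster pair is projected on the line through its empirical centres;
    the reported value is the minimum pairwise index, i.e. the separation of
    the nearest neighbours, the quantity the generator calibrates.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    best = math.inf
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            xa, xb = data[labels == gi], data[labels == gj]
            axis = xb.mean(axis=0) - xa.mean(axis=0)
            norm = np.linalg.norm(axis)
            if norm == 0.0:
                continue
            axis = axis / norm
            idx = estimate_separation_index(xa @ axis, xb @ axis, alpha=alpha)
            best = min(best, idx)
    if not math.isfinite(best):
        raise ValueError("no valid cluster pair found")
    return best
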