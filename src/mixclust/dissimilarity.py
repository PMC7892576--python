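"""Pairwise dissimilarities for mixed data.

Two constructions are provided:

* **Gower**: per-variable similarities — range-normalised absolute
  difference for continuous columns, exact-match (Hamming) indicator for
  categorical columns — averaged over the p variables; the dissimilarity is
  ``1 - S``.
* **UET** (unsupervised extra trees): M fully random trees are grown with
  no target variable; a pair's similarity is the fraction of trees in which
  it co-occurs in a terminal node, and the dissimilarity is ``sqrt(1 - S)``.
  Because splits depend only on orderings and level identities, UET needs
  no prior scaling of the continuous columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MixedDataset

logger = logging.getLogger(__name__)

__all__ = ["DissimilarityMatrix", "UETParams", "gower_dissimilarity", "uet_dissimilarity"]


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative N x N dissimilarities with zero diagonal."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if v.min() < 0.0:
            raise ValueError("dissimilarities must be nonnegative")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class UETParams:
    """UET forest size M and the smoothing (minimum node size) parameter."""

    n_trees: int = 50
    smoothing: int | None = None  # None -> ceil(sqrt(N))

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.smoothing is not None and self.smoothing < 1:
            raise ValueError("smoothing must be >= 1")


def gower_dissimilarity(ds: MixedDataset) -> DissimilarityMatrix:
    """Gower dissimilarity 1 - S with S averaged over all p variables.

    S(x, y) = (1/m) [ sum_j (1 - |x_j - y_j| / Range(j))  +  sum_j 1{x_j = y_j} ]

    with m = p.  A constant continuous column has Range 0; its contribution
    is fixed to full similarity (warning logged) so real data with degenerate
    columns does not produce NaNs.
    """
    n = ds.n_obs
    m = ds.n_variables
    if m == 0:
        raise ValueError("dataset has no variables")
    total = np.zeros((n, n))
    for j in range(ds.n_continuous):
        col = ds.continuous[:, j]
        rng_j = col.max() - col.min()
        if rng_j == 0.0:
            logger.warning(
                "constant continuous column %s: Gower contribution set to full similarity",
                ds.continuous_meta[j].name,
            )
            continue
        total += np.abs(col[:, None] - col[None, :]) / rng_j
    for j in range(ds.n_categorical):
        col = ds.categorical[:, j]
        total += (col[:, None] != col[None, :]).astype(float)
    d = total / m
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=(d + d.T) / 2.0, kind="gower")


def _grow_tree(
    ds: MixedDataset,
    idx: np.ndarray,
    variables: list[tuple[str, int]],
    smoothing: int,
    rng: np.random.Generator,
    cooc: np.ndarray,
) -> None:
    """Recursively split an index set; record leaf co-occurrences in place.

    Variables are consumed without replacement along each root-to-leaf path;
    growth halts when none remain or the node is smaller than the smoothing
    parameter.  A variable that is constant within the node cannot split it
    and is dropped from the path.
    """
    while True:
        if idx.size < smoothing or not variables:
            cooc[np.ix_(idx, idx)] += 1
            return
        k = rng.integers(len(variables))
        kind, col = variables[k]
        remaining = variables[:k] + variables[k + 1 :]
        if kind == "continuous":
            values = ds.continuous[idx, col]
            lo, hi = values.min(), values.max()
            if lo == hi:
                variables = remaining
                continue
            thr = rng.uniform(lo, hi)
            mask = values <= thr
        else:
            values = ds.categorical[idx, col]
            present = np.unique(values)
            if present.size < 2:
                variables = remaining
                continue
            level = rng.choice(present)
            mask = values == level
        _grow_tree(ds, idx[mask], remaining, smoothing, rng, cooc)
        idx, variables = idx[~mask], remaining


def uet_dissimilarity(
    ds: MixedDataset,
    params: UETParams | None = None,
    rng: np.random.Generator | None = None,
) -> DissimilarityMatrix:
    """Unsupervised extra-trees dissimilarity sqrt(1 - S).

    Each of the M trees samples, at every node, a not-yet-used variable and
    a random split: a threshold drawn uniformly between the node's observed
    min and max for a continuous variable, or a uniformly chosen present
    level (equal vs different) for a categorical one.  S is the fraction of
    trees in which a pair shares a terminal node.
    """
    if params is None:
        params = UETParams()
    if rng is None:
        rng = np.random.default_rng()
    n = ds.n_obs
    if n < 2:
        raise ValueError("need at least two observations")
    if ds.n_variables < 1:
        raise ValueError("dataset has no variables")
    smoothing = params.smoothing or int(np.ceil(np.sqrt(n)))
    variables = [("continuous", j) for j in range(ds.n_continuous)] + [
        ("categorical", j) for j in range(ds.n_categorical)
    ]
    cooc = np.zeros((n, n))
    all_idx = np.arange(n)
    for _ in range(params.n_trees):
        _grow_tree(ds, all_idx, list(variables), smoothing, rng, cooc)
    s = cooc / params.n_trees
    d = np.sqrt(np.clip(1.0 - s, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=(d + d.T) / 2.0, kind="uet")
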