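"""Core data containers for mixed-type (continuous + categorical) datasets.

A *mixed dataset* holds N observations over q continuous variables and
p - q categorical variables (level codes 0..L-1 per column).  When the
dataset was simulated, the true partition and per-variable relevance
metadata travel with it so that downstream evaluation can score recovered
partitions against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: degree of relevance -> target nearest-neighbour separation index of the
#: continuous generator
SEP_INDEX_BY_DEGREE: dict[str, float] = {"low": -0.3, "mild": 0.0, "high": 0.3}

#: degree of relevance -> proportion of categorical values resampled
#: uniformly over the levels (higher noise = less relevant)
NOISE_BY_DEGREE: dict[str, float] = {"low": 0.95, "mild": 0.85, "high": 0.75}

DEGREES = ("low", "mild", "high")


@dataclass(frozen=True)
class VariableMeta:
    """Per-variable bookkeeping: name, relevance flag and degree."""

    name: str
    relevant: bool = True
    degree: str = "mild"

    def __post_init__(self) -> None:
        if self.degree not in DEGREES:
            raise ValueError(f"unknown degree {self.degree!r}; expected one of {DEGREES}")


@dataclass
class MixedDataset:
    """Typed table of N observations over mixed continuous/categorical columns.

    Parameters
    ----------
    continuous
        Float matrix of shape (N, q); q may be 0.
    categorical
        Integer level-code matrix of shape (N, p - q); codes in
        ``0..level_counts[j] - 1``.
    level_counts
        Number of levels of each categorical column.
    true_labels
        Optional ground-truth cluster index per row (0..G-1), present for
        simulated data.
    continuous_meta, categorical_meta
        Optional per-variable relevance metadata.
    """

    continuous: np.ndarray
    categorical: np.ndarray
    level_counts: np.ndarray
    true_labels: Optional[np.ndarray] = None
    continuous_meta: list[VariableMeta] = field(default_factory=list)
    categorical_meta: list[VariableMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.continuous = np.asarray(self.continuous, dtype=float)
        self.categorical = np.asarray(self.categorical, dtype=np.int64)
        self.level_counts = np.asarray(self.level_counts, dtype=np.int64)
        if self.continuous.ndim != 2 or self.categorical.ndim != 2:
            raise ValueError("continuous and categorical must be 2-D matrices")
        n_cont, n_cat = self.continuous.shape[0], self.categorical.shape[0]
        if self.n_continuous and self.n_categorical and n_cont != n_cat:
            raise ValueError(f"row mismatch: {n_cont} continuous vs {n_cat} categorical rows")
        if self.level_counts.shape[0] != self.n_categorical:
            raise ValueError("level_counts must have one entry per categorical column")
        if self.n_categorical:
            if self.categorical.min(initial=0) < 0 or np.any(
                self.categorical.max(axis=0, initial=0) >= self.level_counts
            ):
                raise ValueError("categorical codes must lie in 0..level_count-1 per column")
        if self.n_obs < 1:
            raise ValueError("dataset must contain at least one observation")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
            if self.true_labels.shape != (self.n_obs,):
                raise ValueError("true_labels length must equal the number of rows")
            g = int(self.true_labels.max()) + 1
            if not np.array_equal(np.unique(self.true_labels), np.arange(g)):
                raise ValueError("true_labels must use every label in 0..G-1 at least once")
        if not self.continuous_meta:
            self.continuous_meta = [VariableMeta(f"num{j + 1}") for j in range(self.n_continuous)]
        if not self.categorical_meta:
            self.categorical_meta = [VariableMeta(f"cat{j + 1}") for j in range(self.n_categorical)]
        if len(self.continuous_meta) != self.n_continuous:
            raise ValueError("continuous_meta length mismatch")
        if len(self.categorical_meta) != self.n_categorical:
            raise ValueError("categorical_meta length mismatch")

    @property
    def n_obs(self) -> int:
        return self.continuous.shape[0] if self.n_continuous else self.categorical.shape[0]

    @property
    def n_continuous(self) -> int:
        return self.continuous.shape[1]

    @property
    def n_categorical(self) -> int:
        return self.categorical.shape[1]

    @property
    def n_variables(self) -> int:
        return self.n_continuous + self.n_categorical

    @property
    def n_clusters(self) -> Optional[int]:
        if self.true_labels is None:
            return None
        return int(self.true_labels.max()) + 1

    def copy(self) -> "MixedDataset":
        return replace(
            self,
            continuous=self.continuous.copy(),
            categorical=self.categorical.copy(),
            level_counts=self.level_counts.copy(),
            true_labels=None if self.true_labels is None else self.true_labels.copy(),
            continuous_meta=list(self.continuous_meta),
            categorical_meta=list(self.categorical_meta),
        )


@dataclass
class Partition:
    """Hard assignment of N observations to G clusters (labels 0..G-1)."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a vector")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_clusters):
            raise ValueError("labels out of range 0..G-1")

    @property
    def n_obs(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation condition: sizes, counts, relevance proportions/degrees.

    Defaults are the benchmark baseline: N=300, G=6, 4 continuous + 4
    categorical variables, all relevant at the mild degree.
    """

    population_size: int = 300
    n_clusters: int = 6
    n_continuous: int = 4
    n_categorical: int = 4
    prop_relevant_continuous: float = 1.0
    prop_relevant_categorical: float = 1.0
    degree_continuous: str = "mild"
    degree_categorical: str = "mild"
    label: str = "default"
    #: escape hatches for conditions outside the low/mild/high grid, e.g. a
    #: noise-free sanity scenario; None defers to the degree mapping
    sep_index_override: float | None = None
    noise_prop_override: float | None = None

    def __post_init__(self) -> None:
        if self.population_size < self.n_clusters:
            raise ValueError("population_size must be >= n_clusters")
        if self.n_clusters < 2:
            raise ValueError("need at least two clusters")
        if self.n_continuous < 0 or self.n_categorical < 0:
            raise ValueError("variable counts must be nonnegative")
        if self.n_continuous + self.n_categorical == 0:
            raise ValueError("need at least one variable")
        for prop, kind in (
            (self.prop_relevant_continuous, "continuous"),
            (self.prop_relevant_categorical, "categorical"),
        ):
            if not 0.0 < prop <= 1.0:
                raise ValueError(f"prop_relevant_{kind} must lie in (0, 1]")
        for degree in (self.degree_continuous, self.degree_categorical):
            if degree not in DEGREES:
                raise ValueError(f"unknown degree {degree!r}")
        if self.sep_index_override is not None and not -2.0 < self.sep_index_override < 2.0:
            raise ValueError("separation index must lie in ]-2, +2[")
        if self.noise_prop_override is not None and not 0.0 <= self.noise_prop_override <= 1.0:
            raise ValueError("noise proportion must lie in [0, 1]")

    @property
    def sep_index(self) -> float:
        if self.sep_index_override is not None:
            return self.sep_index_override
        return SEP_INDEX_BY_DEGREE[self.degree_continuous]

    @property
    def noise_prop(self) -> float:
        if self.noise_prop_override is not None:
            return self.noise_prop_override
        return NOISE_BY_DEGREE[self.degree_categorical]

    def n_relevant(self, kind: str) -> int:
        total = self.n_continuous if kind == "continuous" else self.n_categorical
        prop = (
            self.prop_relevant_continuous
            if kind == "continuous"
            else self.prop_relevant_categorical
        )
        n_irrelevant = int(round((1.0 - prop) * total))
        return total - n_irrelevant


def as_partition(labels: Sequence[int] | np.ndarray, n_clusters: Optional[int] = None) -> Partition:
    labels = np.asarray(labels, dtype=np.int64)
    if n_clusters is None:
        n_clusters = int(labels.max()) + 1 if labels.size else 0
    return Partition(labels=labels, n_clusters=n_clusters)
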