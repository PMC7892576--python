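"""Adjusted-Rand-Index evaluation and the replicated scenario benchmark.

Nine clustering strategies are registered under short names:

========  =====================================================
name      pipeline
========  =====================================================
gower_pam Gower dissimilarity + partitioning around medoids
gower_hc  Gower dissimilarity + Ward hierarchical clustering
uet_pam   extra-trees dissimilarity + PAM
uet_hc    extra-trees dissimilarity + Ward HC
kproto    k-prototypes on the mixed table
kamila    semiparametric KDE/multinomial alternation
mixmod    diagonal normal-multinomial mixture EM (single run)
lcm       same mixture with multi-start small EM
lca       multinomial mixture on tertile-discretised data
========  =====================================================

Every method receives the same scaled dataset and the true number of
clusters; the recovered partition is scored against the ground truth with
the adjusted Rand index.  Replicates are seeded independently per
(scenario, level, replicate), and each method consumes its own child
stream, so adding a method never perturbs the others' results.
"""

from __future__ import annotations

import logging
import time
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import MixedDataset, Partition, ScenarioSpec
from .dissimilarity import UETParams, gower_dissimilarity, uet_dissimilarity
from .distance_clustering import hac_ward, kprototypes, pam
from .model_clustering import kamila, lca_pipeline, lcm_cluster, mixmod_cluster
from .simulate import generate_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "adjusted_rand_index",
    "METHODS",
    "run_method",
    "run_benchmark",
    "summarize",
]


def adjusted_rand_index(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Hubert-Arabie adjusted Rand index between two hard partitions.

    Computed from the contingency table n_ij with margins a_i, b_j:

        ARI = (sum_ij C(n_ij,2) - E) / (0.5 [sum_i C(a_i,2) + sum_j C(b_j,2)] - E),
        E   = sum_i C(a_i,2) sum_j C(b_j,2) / C(N,2).

    Equals 1 iff the partitions coincide up to relabelling; 0 in expectation
    for independent partitions; can be negative.
    """
    x = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    y = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if x.shape != y.shape:
        raise ValueError("partitions must have equal length")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (xi, yi), 1)

    def comb2(v: np.ndarray) -> float:
        return float((v * (v - 1) / 2.0).sum())

    sum_ij = comb2(table)
    sum_a = comb2(table.sum(axis=1))
    sum_b = comb2(table.sum(axis=0))
    total = n * (n - 1) / 2.0
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons or one block)
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# method registry

MethodFn = Callable[[MixedDataset, int, np.random.Generator, dict], Partition]


def _gower(ds: MixedDataset, shared: dict) -> np.ndarray:
    if "gower" not in shared:
        shared["gower"] = gower_dissimilarity(ds)
    return shared["gower"]


def _uet(ds: MixedDataset, rng: np.random.Generator, shared: dict) -> np.ndarray:
    # one forest per dataset, shared by uet_pam and uet_hc, grown from the
    # dedicated "uet" resource stream
    if "uet" not in shared:
        shared["uet"] = uet_dissimilarity(ds, UETParams(), rng)
    return shared["uet"]


def _m_gower_pam(ds, G, rng, shared):
    return pam(_gower(ds, shared), G)[0]


def _m_gower_hc(ds, G, rng, shared):
    return hac_ward(_gower(ds, shared), G)


def _m_uet_pam(ds, G, rng, shared):
    return pam(_uet(ds, rng, shared), G)[0]


def _m_uet_hc(ds, G, rng, shared):
    return hac_ward(_uet(ds, rng, shared), G)


def _m_kproto(ds, G, rng, shared):
    return kprototypes(ds, G, rng=rng)[0]


def _m_kamila(ds, G, rng, shared):
    return kamila(ds, G, rng=rng)[0]


def _m_mixmod(ds, G, rng, shared):
    return mixmod_cluster(ds, G, rng=rng)[0]


def _m_lcm(ds, G, rng, shared):
    return lcm_cluster(ds, G, rng=rng)[0]


def _m_lca(ds, G, rng, shared):
    return lca_pipeline(ds, G, rng=rng)[0]


#: registry; the position index doubles as the method's stable seed id
METHODS: dict[str, MethodFn] = {
    "gower_pam": _m_gower_pam,
    "gower_hc": _m_gower_hc,
    "uet_pam": _m_uet_pam,
    "uet_hc": _m_uet_hc,
    "kproto": _m_kproto,
    "kamila": _m_kamila,
    "mixmod": _m_mixmod,
    "lcm": _m_lcm,
    "lca": _m_lca,
}

_METHOD_SEED_ID = {name: i + 2 for i, name in enumerate(METHODS)}
_DATA_SEED_ID = 0
_UET_SEED_ID = 1


def run_method(
    name: str,
    ds: MixedDataset,
    n_clusters: int,
    rng: np.random.Generator,
    shared: dict | None = None,
) -> Partition:
    """Run one registered method on a dataset with the true G."""
    if name not in METHODS:
        raise KeyError(f"unknown method {name!r}; available: {sorted(METHODS)}")
    return METHODS[name](ds, n_clusters, rng, {} if shared is None else shared)


def _child_rng(master_seed: int, scen_idx: int, rep: int, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(scen_idx), int(rep), int(stream_id)])
    )


def run_benchmark(
    scenarios: Sequence[ScenarioSpec],
    methods: Sequence[str] | None = None,
    n_reps: int = 1000,
    master_seed: int = 0,
    scenario_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Replicated ARI benchmark over scenario levels and methods.

    For each scenario level and replicate, a dataset is generated and scaled
    from the level's own seed stream, then fed identically to every
    requested method with G = the true number of clusters.  Method failures
    are recorded (ARI = NaN plus the error text), never raised, so a long
    unattended sweep always completes.

    Returns a long-format table with one row per (level, method, replicate).
    """
    method_names = list(METHODS) if methods is None else list(methods)
    unknown = [m for m in method_names if m not in METHODS]
    if unknown:
        raise KeyError(f"unknown methods {unknown}; available: {sorted(METHODS)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if scenario_ids is None:
        scenario_ids = list(range(len(scenarios)))
    records = []
    for scen_idx, spec in zip(scenario_ids, scenarios):
        for rep in range(n_reps):
            data_rng = _child_rng(master_seed, scen_idx, rep, _DATA_SEED_ID)
            ds = generate_scenario(spec, data_rng)
            truth = ds.true_labels
            shared: dict = {}
            # the shared UET forest uses its own stream so the pam/hc pair
            # sees a single forest regardless of which of them runs first
            uet_rng = _child_rng(master_seed, scen_idx, rep, _UET_SEED_ID)
            for name in method_names:
                rng = (
                    uet_rng
                    if name.startswith("uet_")
                    else _child_rng(master_seed, scen_idx, rep, _METHOD_SEED_ID[name])
                )
                t0 = time.perf_counter()
                try:
                    part = run_method(name, ds, spec.n_clusters, rng, shared)
                    ari = adjusted_rand_index(part.labels, truth)
                    err = ""
                except Exception as exc:  # failure is a result, not an abort
                    logger.warning("method %s failed on rep %d: %s", name, rep, exc)
                    ari, err = np.nan, f"{type(exc).__name__}: {exc}"
                records.append(
                    {
                        "scenario": spec.label,
                        "method": name,
                        "replicate": rep,
                        "seed": master_seed,
                        "ari": ari,
                        "seconds": time.perf_counter() - t0,
                        "error": err,
                    }
                )
    return pd.DataFrame.from_records(records)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Classical univariate statistics of ARI per (scenario level, method).

    Failed replicates are excluded from the moments but counted under
    ``failures``.
    """
    if results.empty:
        raise ValueError("no benchmark records to summarize")

    def _agg(group: pd.DataFrame) -> pd.Series:
        ari = group["ari"].dropna()
        return pd.Series(
            {
                "n": len(group),
                "failures": int(group["ari"].isna().sum()),
                "mean": ari.mean(),
                "sd": ari.std(ddof=1),
                "median": ari.median(),
                "q25": ari.quantile(0.25),
                "q75": ari.quantile(0.75),
            }
        )

    out = (
        results.groupby(["scenario", "method"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    out["failures"] = out["failures"].astype(int)
    return out
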