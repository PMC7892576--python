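"""Typed-CSV dataset I/O, scenario presets and result plumbing.

A dataset travels as a pair of files: a plain CSV with one header row, and
a JSON *manifest* declaring each column's type (continuous or categorical),
its level list for categorical columns, and its relevance metadata.  Level
order in the manifest defines the 0-based integer coding, so a
write -> read round trip is lossless and platform-stable.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MixedDataset, ScenarioSpec, VariableMeta
from .dissimilarity import DissimilarityMatrix

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_labels",
    "read_labels",
    "write_dissimilarity",
    "read_dissimilarity",
    "load_scenario",
    "PRESET_NAMES",
]

PRESET_NAMES = tuple(str(i) for i in range(1, 8))


def _manifest_entry(meta: VariableMeta, kind: str, n_levels: int | None = None) -> dict:
    entry = {
        "name": meta.name,
        "type": kind,
        "relevant": bool(meta.relevant),
        "degree": meta.degree,
    }
    if kind == "categorical":
        entry["n_levels"] = int(n_levels)
        entry["levels"] = [f"l{code}" for code in range(n_levels)]
    return entry


def write_dataset(ds: MixedDataset, csv_path: str | Path, manifest_path: str | Path) -> None:
    """Write a dataset as CSV + JSON manifest (categorical cells as level names)."""
    columns: dict[str, object] = {}
    variables = []
    for j, meta in enumerate(ds.continuous_meta):
        columns[meta.name] = ds.continuous[:, j]
        variables.append(_manifest_entry(meta, "continuous"))
    for j, meta in enumerate(ds.categorical_meta):
        n_levels = int(ds.level_counts[j])
        columns[meta.name] = [f"l{code}" for code in ds.categorical[:, j]]
        variables.append(_manifest_entry(meta, "categorical", n_levels))
    pd.DataFrame(columns).to_csv(csv_path, index=False)
    manifest = {
        "n_obs": int(ds.n_obs),
        "n_clusters": None if ds.true_labels is None else int(ds.n_clusters),
        "variables": variables,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_dataset(
    csv_path: str | Path,
    manifest_path: str | Path,
    labels_path: str | Path | None = None,
) -> MixedDataset:
    """Read a CSV + manifest pair back into a :class:`MixedDataset`."""
    manifest = json.loads(Path(manifest_path).read_text())
    declared = [v["name"] for v in manifest["variables"]]
    header = list(pd.read_csv(csv_path, nrows=0).columns)
    if header != declared:
        raise ValueError(
            f"manifest/header mismatch: CSV columns {header} vs manifest {declared}"
        )
    table = pd.read_csv(csv_path, dtype=str)
    cont_cols, cont_meta = [], []
    cat_cols, cat_meta, level_counts = [], [], []
    for var in manifest["variables"]:
        name = var["name"]
        meta = VariableMeta(name, relevant=var.get("relevant", True), degree=var.get("degree", "mild"))
        raw = table[name]
        if var["type"] == "continuous":
            try:
                cont_cols.append(raw.astype(float).to_numpy())
            except ValueError as exc:
                raise ValueError(f"column {name!r}: non-numeric continuous value ({exc})")
            cont_meta.append(meta)
        elif var["type"] == "categorical":
            levels = var["levels"]
            code_of = {lvl: i for i, lvl in enumerate(levels)}
            codes = raw.map(code_of)
            if codes.isna().any():
                row = int(codes.index[codes.isna()][0])
                raise ValueError(
                    f"column {name!r}, row {row}: level {raw.iloc[row]!r} "
                    f"not among declared levels {levels}"
                )
            cat_cols.append(codes.to_numpy(dtype=np.int64))
            cat_meta.append(meta)
            level_counts.append(len(levels))
        else:
            raise ValueError(f"column {name!r}: unknown type {var['type']!r}")
    n = len(table)
    labels = read_labels(labels_path) if labels_path is not None else None
    return MixedDataset(
        continuous=np.column_stack(cont_cols) if cont_cols else np.empty((n, 0)),
        categorical=np.column_stack(cat_cols) if cat_cols else np.empty((n, 0), dtype=np.int64),
        level_counts=np.asarray(level_counts, dtype=np.int64),
        true_labels=labels,
        continuous_meta=cont_meta,
        categorical_meta=cat_meta,
    )


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"label": np.asarray(labels, dtype=np.int64)}).to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=np.int64)


def write_dissimilarity(D: DissimilarityMatrix, path: str | Path) -> None:
    ids = [str(i) for i in range(D.n_obs)]
    pd.DataFrame(D.values, index=ids, columns=ids).to_csv(path)


def read_dissimilarity(path: str | Path, kind: str = "gower") -> DissimilarityMatrix:
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy(dtype=float)
    # enforce exact symmetry lost to decimal round-tripping
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(values=values, kind=kind)


def _spec_from_dict(payload: dict) -> ScenarioSpec:
    return ScenarioSpec(**payload)


def load_scenario(source: str | Path) -> list[ScenarioSpec]:
    """Load a scenario: preset name "1".."7" or a path to a JSON file.

    A scenario file holds ``{"scenario": ..., "levels": [{spec fields}]}``;
    each level becomes one :class:`ScenarioSpec`.
    """
    name = str(source)
    if name in PRESET_NAMES:
        payload = json.loads(
            resources.files("mixclust").joinpath("presets", f"scenario{name}.json").read_text()
        )
    else:
        path = Path(source)
        if not path.exists():
            raise ValueError(
                f"unknown scenario {source!r}: not a file and not one of presets {list(PRESET_NAMES)}"
            )
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed scenario JSON {source}: {exc}")
    if "levels" not in payload or not payload["levels"]:
        raise ValueError(f"scenario {source!r} declares no levels")
    return [_spec_from_dict(level) for level in payload["levels"]]
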