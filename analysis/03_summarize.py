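#!/usr/bin/env python
"""Summarise benchmark results and draw per-scenario ARI boxplots.

Reads the long-format CSVs written by 02_benchmark.py, writes one summary
table per scenario (mean/sd/median/quartiles/failures per condition and
method) under results/summary/, a boxplot panel per scenario under
results/figures/, and prints the headline comparison: median ARI per method
at the baseline condition, ordered best to worst.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from mixclust import summarize

MODEL_BASED = {"kamila", "mixmod", "lcm", "lca"}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results/benchmark"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    (args.out / "summary").mkdir(parents=True, exist_ok=True)
    (args.out / "figures").mkdir(parents=True, exist_ok=True)

    for path in sorted(args.results.glob("scenario*.csv")):
        frame = pd.read_csv(path, keep_default_na=True)
        frame["error"] = frame.get("error", "")
        table = summarize(frame)
        table.to_csv(args.out / "summary" / path.name, index=False)

        levels = list(dict.fromkeys(frame["scenario"]))
        fig, axes = plt.subplots(
            1, len(levels), figsize=(3.2 * len(levels), 4), squeeze=False, sharey=True
        )
        for ax, level in zip(axes[0], levels):
            sub = frame[frame["scenario"] == level].dropna(subset=["ari"])
            order = list(dict.fromkeys(sub["method"]))
            ax.boxplot(
                [sub[sub["method"] == m]["ari"] for m in order], tick_labels=order
            )
            ax.set_title(str(level))
            ax.tick_params(axis="x", rotation=60)
        axes[0][0].set_ylabel("ARI vs true partition")
        fig.tight_layout()
        fig.savefig(args.out / "figures" / path.with_suffix(".png").name, dpi=120)
        plt.close(fig)

        if path.stem == "scenario1":
            base = frame[frame["scenario"] == "N=300"]
            med = base.groupby("method")["ari"].median().sort_values(ascending=False)
            print("baseline condition (N=300), median ARI best to worst:")
            for method, value in med.items():
                kind = "model-based" if method in MODEL_BASED else "distance-based"
                print(f"  {method:<10} {value:.3f}  ({kind})")
    print(f"summaries under {args.out}/summary, figures under {args.out}/figures")


if __name__ == "__main__":
    main()
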