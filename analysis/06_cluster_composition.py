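#!/usr/bin/env python
"""Cluster the molecules in PC space (cluster count from the elbow of the
within-cluster-sum-of-squares curve) and tabulate, for the 7 most frequent
descriptors, the percentage of each descriptor's positive molecules falling
in each cluster — the radar-chart composition table.
"""

import argparse
from pathlib import Path

import smellbench as sb
from smellbench import io_core


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=7)
    args = ap.parse_args()

    labels = io_core.read_label_matrix(args.data_dir / "labels.csv")
    for name in ("enose", "descriptors"):
        path = args.out_dir / f"scores_{name}.csv"
        if not path.exists():
            continue
        scores = io_core.read_feature_table(path, provenance="synthetic")
        k_range = range(1, 11)
        k = sb.elbow_select(scores, k_range)
        curve = sb.elbow_curve(scores, k_range)
        curve.rename_axis("k").to_csv(args.out_dir / f"elbow_{name}.csv")
        assignments = sb.cluster_molecules(scores, k)
        result = sb.descriptor_percentages(assignments, labels, top_n=args.top)
        io_core.write_results(result.to_frame(),
                              args.out_dir / f"composition_{name}.csv",
                              extra={"n_clusters": k})
        print(f"\n{name}: elbow-selected k = {k}")
        print(result.percentages.round(2).to_string())
        peak = result.percentages.max(axis=1)
        spread = (result.percentages > 0).sum(axis=1)
        print(f"most concentrated descriptor: {peak.idxmax()} "
              f"({peak.max():.1f}% in one cluster; positives spread over "
              f"{spread[peak.idxmax()]} clusters)")


if __name__ == "__main__":
    main()
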