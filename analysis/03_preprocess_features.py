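#!/usr/bin/env python
"""Normalize each featurization to [0,1] and PCA-reduce at the 0.95
cumulative-variance cutoff, reporting original vs reduced dimensions (the
synthetic counterpart of the study's dimension table: the e-nose channels
are highly correlated and collapse to ~5 components, the wider modalities
keep more).  Writes the score tables and the dimension summary.
"""

import argparse
from pathlib import Path

import pandas as pd

import smellbench as sb
from smellbench import io_core


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--cutoff", type=float, default=0.95)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = []
    for path in sorted(args.data_dir.glob("features_*.csv")):
        name = path.stem.removeprefix("features_")
        table = io_core.read_feature_table(path, provenance="synthetic")
        scores, _, reduction = sb.preprocess_table(table, cutoff=args.cutoff)
        io_core.write_feature_table(scores, args.out_dir / f"scores_{name}.csv")
        rows.append({"feature_set": name,
                     "original_dimension": table.n_features,
                     "reduced_dimension": reduction.n_components,
                     "cumulative_variance": round(reduction.cumulative_variance, 4)})
    spectra = {p.stem: io_core.read_spectrum(p)
               for p in sorted((args.data_dir / "spectra").glob("*.csv"))}
    if spectra:
        sm = sb.build_spectrum_matrix(spectra)
        scores, _, reduction = sb.preprocess_table(sm.table, cutoff=args.cutoff)
        io_core.write_feature_table(scores, args.out_dir / "scores_spectrum_union.csv")
        rows.append({"feature_set": "spectrum_union",
                     "original_dimension": sm.table.n_features,
                     "reduced_dimension": reduction.n_components,
                     "cumulative_variance": round(reduction.cumulative_variance, 4)})
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out_dir / "dimension_table.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
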