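#!/usr/bin/env python
"""Recompute the measured cohort's deterministic numbers from the study's
supplementary workbook (S1 data): molecule and descriptor counts, top
descriptor positives, and the e-nose PCA dimension at the 0.95 cutoff.

The workbook is not redistributable with this repository; download
pone.0289881.s001 from the journal and place it at data/pone.0289881.s001.xlsx
(or pass --workbook).  Without it this driver prints the instructions and
the expected values, and exits.
"""

import argparse
import json
from pathlib import Path

from smellbench.experiments import STUDY_EXPECTATIONS, reproduce_supplementary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--workbook", type=Path,
                    default=Path("data/pone.0289881.s001.xlsx"))
    ap.add_argument("--out", type=Path, default=Path("results/s1_reproduction.json"))
    args = ap.parse_args()

    if not args.workbook.exists():
        print(f"workbook not found at {args.workbook}")
        print("download the study's S1 data (supplementary file "
              "pone.0289881.s001, XLSX) and place it there.")
        print("expected values once available:",
              json.dumps(STUDY_EXPECTATIONS, indent=2))
        return

    repro = reproduce_supplementary(args.workbook)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(repro.as_dict(), indent=2))
    print(json.dumps(repro.as_dict(), indent=2))
    for key in ("n_molecules", "n_descriptors"):
        got, want = getattr(repro, key), STUDY_EXPECTATIONS[key]
        print(f"{key}: {got} (study: {want}) {'OK' if got == want else 'MISMATCH'}")


if __name__ == "__main__":
    main()
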