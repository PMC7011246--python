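#!/usr/bin/env python
"""Extract the canonical 152-feature texture vector for every subject.

Reads the cohort written by 01_simulate_cohort.py, normalizes each ROI's
intensities to [0, 1] inside its mask, and writes results/features.csv
(one row per subject, 152 named feature columns in canonical order).
"""

import argparse
from pathlib import Path

from radiotex.features import extract_table
from radiotex.io_preprocess import normalize_roi
from radiotex.synthetic import load_cohort_dir


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = ap.parse_args()

    rois, _ = load_cohort_dir(args.cohort)
    table = extract_table(normalize_roi(r) for r in rois)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out)
    print(f"extracted {table.shape[1]} features for {table.shape[0]} subjects -> {args.out}")
    named = ["grad.glrm.lre", "wav_d.fos.mean", "wav_v.glrm.lgre", "hog.fos.entropy"]
    print("\nselected named features (first subjects):")
    print(table[named].head(4).round(4))


if __name__ == "__main__":
    main()
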