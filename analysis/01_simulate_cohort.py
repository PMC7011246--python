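#!/usr/bin/env python
"""Generate the synthetic two-arm study cohort and write it to disk.

Produces results/cohort/{images,masks}/*.png and results/cohort/metadata.csv:
8 control + 8 treated subjects whose tumor texture differs by random-field
correlation length, with survival linked to the realized texture parameter
and histology markers linked to designated image features.
"""

import argparse
from pathlib import Path

from radiotex.synthetic import SyntheticCohortConfig, generate_cohort, save_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cohort = generate_cohort(SyntheticCohortConfig(seed=args.seed))
    out = save_cohort(cohort, args.out)
    meta = cohort.metadata()
    print(f"wrote {len(cohort.subjects)} subjects to {out}")
    print("\noverall survival by arm (days):")
    print(meta.groupby("group")["survival_days"].agg(["mean", "std"]).round(2))
    print("\nhistology marker summary:")
    print(meta[["fibrosis_pct", "ck19_pct", "ki67_per_field"]].describe().loc[["mean", "std"]].round(2))


if __name__ == "__main__":
    main()
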