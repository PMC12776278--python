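#!/usr/bin/env python
"""Longitudinal statistics: within-group paired contrasts and between-group
dynamics.

For each transplant group, compares tissue roles (Before/After/Native) with
a paired model (donor as covariate) on the predicted ages; then tests every
pair of groups for differential Before->After dynamics via the stage x group
interaction on the sham-calibrated age deviations. BH adjustment is applied
within each family (one family per clock for the within-group contrasts;
the six group pairs form the interaction family).
"""

import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from adipoclock import io, longstats
from adipoclock.types import TRANSPLANT_GROUPS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    sheet = io.read_sample_sheet(args.data / "sample_sheet.csv")
    rows = []
    for label, path in (("tAge", "tage_predictions.tsv"), ("eAge", "eage_predictions.tsv")):
        preds = pd.read_csv(args.out / path, sep="\t").set_index("sample_id")["prediction"]
        family = []
        for g in TRANSPLANT_GROUPS:
            for r in longstats.paired_contrast(preds, sheet[sheet["group"] == g]):
                family.append((g, r))
        longstats.adjust_family([r for _, r in family])
        for g, r in family:
            rows.append((label, g, r.term, r.estimate, r.se, r.p, r.p_adj, r.n))
        after = {g: r for g, r in family if r.term == "role[after]"}
        sig = {g: "*" if after[g].p_adj < 0.05 else " " for g in TRANSPLANT_GROUPS}
        print(f"{label} Before->After estimates: " + ", ".join(
            f"{g} {after[g].estimate:+.2f}{sig[g]}" for g in TRANSPLANT_GROUPS
        ))
    within = pd.DataFrame(
        rows, columns=["clock", "group", "term", "estimate", "se", "p", "p_adj", "n"]
    )
    within.to_csv(args.out / "within_group_contrasts.tsv", sep="\t", index=False)

    dev = pd.read_csv(args.out / "age_deviations.tsv", sep="\t").set_index("sample_id")["age_deviation"]
    inter = [
        (f"{a}_vs_{b}", longstats.interaction_contrast(dev, sheet, (a, b)))
        for a, b in combinations(TRANSPLANT_GROUPS, 2)
    ]
    longstats.adjust_family([r for _, r in inter])
    pd.DataFrame(
        [
            (k, r.estimate, r.se, r.p, r.p_adj, r.n)
            for k, r in inter
        ],
        columns=["comparison", "estimate", "se", "p", "p_adj", "n"],
    ).to_csv(args.out / "dynamics_interactions.tsv", sep="\t", index=False)
    sig = [k for k, r in inter if r.p_adj < 0.05]
    print(f"group pairs with significantly different age dynamics (q<0.05): {sig}")


if __name__ == "__main__":
    main()
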