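#!/usr/bin/env python
"""Apply the clocks: preprocessing, tAge/eAge prediction, sham calibration.

Filters the count matrix (>=10 reads in >=20% of samples), runs the
five-step clock preprocessing (RLE -> log2 -> z-scale -> impute -> center to
the young-donor-before median profile), predicts transcriptomic age,
calibrates expected age on the sham controls and writes per-sample age
deviations. The methylation arm filters CpGs by detection p, computes mean
methylation and Shannon entropy per sample, and predicts epigenetic age
directly from beta values.
"""

import argparse
from pathlib import Path

import pandas as pd

from adipoclock import clockcore, io, longstats


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sheet = io.read_sample_sheet(args.data / "sample_sheet.csv")
    counts = io.read_matrix(args.data / "counts.tsv", "counts")
    tclock = io.read_clock(args.data / "transcriptomic_clock.json")

    filtered = clockcore.filter_expression(counts)
    print(f"expression filter kept {filtered.data.shape[0]}/{counts.data.shape[0]} genes")
    processed = clockcore.preprocess_for_clock(filtered, tclock, sheet)
    tpred = clockcore.predict_age(tclock, processed)
    tpred.to_csv(args.out / "tage_predictions.tsv", sep="\t", index=False)

    tage = tpred.set_index("sample_id")["prediction"]
    sham = sheet[sheet["group"] == "SHAM"]
    calib = longstats.sham_calibrate(
        sham["age_months"].to_numpy(), tage.loc[sham["sample_id"]].to_numpy()
    )
    dev = longstats.age_deviation(
        calib, sheet["age_months"].to_numpy(), tage.loc[sheet["sample_id"]].to_numpy()
    )
    pd.DataFrame({"sample_id": sheet["sample_id"], "age_deviation": dev}).to_csv(
        args.out / "age_deviations.tsv", sep="\t", index=False
    )
    print(
        f"sham calibration over {calib.n} samples: expected tAge = "
        f"{calib.intercept:.3f} + {calib.slope:.3f} x age (residual sd {calib.residual_sd:.3f})"
    )

    beta = io.read_matrix(args.data / "beta.csv", "beta")
    detp = pd.read_csv(args.data / "detection_p.csv", index_col=0)
    eclock = io.read_clock(args.data / "epigenetic_clock.json")
    kept = clockcore.filter_methylation(beta, detp)
    print(f"CpG detection filter kept {kept.data.shape[0]}/{beta.data.shape[0]} CpGs")
    summary = pd.DataFrame(
        {
            "mean_methylation": clockcore.mean_methylation(kept),
            "shannon_entropy": clockcore.shannon_entropy(kept),
        }
    )
    summary.to_csv(args.out / "methylation_summary.tsv", sep="\t")
    epred = clockcore.predict_age(eclock, clockcore.impute_features(kept.data, eclock))
    epred.to_csv(args.out / "eage_predictions.tsv", sep="\t", index=False)
    print(f"wrote tAge/eAge predictions and methylation summaries to {args.out}")


if __name__ == "__main__":
    main()
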