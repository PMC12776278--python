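"""Linear clock application and omics preprocessing.

Implements the expression/methylation preprocessing used for transcriptomic
and epigenetic age estimation:

* gene expression filter (>= 10 reads in >= 20% of samples),
* CpG detection-p filter (drop CpGs with detection p > 0.01 in >= 25% of
  samples),
* per-sample mean methylation and Shannon entropy,
* relative log expression (RLE, median-of-ratios) size factors,
* the five-step clock preprocessing pipeline
  (RLE -> log2(x+1) -> per-feature z-scale -> impute missing clock features ->
  center to the reference-group median profile),
* linear clock prediction and within-group standardization of predictions.

Entropy here is the mean per-CpG binary entropy of the methylation fraction
(base-2 logs, so a fully random CpG contributes 1 bit), a standard proxy for
stochastic epigenetic disorder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ClockModel, OmicsMatrix, ProcessedMatrix

ENTROPY_CLAMP = 1e-6

PREPROCESS_STEPS = (
    "rle_normalize",
    "log2_plus_one",
    "zscale_features",
    "impute_clock_features",
    "center_to_reference_median",
)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_expression(counts: OmicsMatrix, min_reads: int = 10, min_fraction: float = 0.2) -> OmicsMatrix:
    """Keep genes with >= ``min_reads`` reads in >= ``min_fraction`` of samples.

    Both comparisons are inclusive: a gene with exactly 10 reads in exactly
    20% of samples is retained. The sample set is unchanged.
    """
    if counts.modality != "counts":
        raise ValueError("filter_expression expects a counts matrix")
    if counts.data.size == 0:
        raise ValueError("cannot filter an empty count matrix")
    frac = (counts.data.to_numpy() >= min_reads).mean(axis=1)
    keep = frac >= min_fraction
    return OmicsMatrix(counts.data.loc[keep], "counts")


def filter_methylation(
    beta: OmicsMatrix,
    detection_p: pd.DataFrame,
    p_thresh: float = 0.01,
    frac: float = 0.25,
) -> OmicsMatrix:
    """Drop CpGs with detection p > ``p_thresh`` in >= ``frac`` of samples."""
    if beta.modality != "beta":
        raise ValueError("filter_methylation expects a beta matrix")
    if beta.data.shape != detection_p.shape:
        raise ValueError(
            f"beta {beta.data.shape} and detection-p {detection_p.shape} matrices differ in shape"
        )
    bad_frac = (detection_p.to_numpy() > p_thresh).mean(axis=1)
    keep = bad_frac < frac
    return OmicsMatrix(beta.data.loc[keep], "beta")


# ---------------------------------------------------------------------------
# Methylation summaries
# ---------------------------------------------------------------------------

def mean_methylation(beta: OmicsMatrix) -> pd.Series:
    """Arithmetic mean methylation fraction per sample over retained CpGs."""
    if beta.data.shape[0] == 0:
        raise ValueError("no CpGs retained: cannot compute mean methylation")
    return beta.data.mean(axis=0).rename("mean_methylation")


def shannon_entropy(beta: OmicsMatrix) -> pd.Series:
    """Mean per-CpG binary entropy (bits) per sample.

    beta is clamped to [1e-6, 1 - 1e-6] before taking logs, so fully
    (un)methylated CpGs contribute ~2.1e-5 bits rather than NaN.
    """
    b = np.clip(beta.data.to_numpy(dtype=float), ENTROPY_CLAMP, 1.0 - ENTROPY_CLAMP)
    h = -(b * np.log2(b) + (1.0 - b) * np.log2(1.0 - b))
    return pd.Series(h.mean(axis=0), index=beta.data.columns, name="shannon_entropy")


# ---------------------------------------------------------------------------
# RLE normalization
# ---------------------------------------------------------------------------

def rle_size_factors(counts: OmicsMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios (RLE) size factor per sample.

    The reference profile is the per-gene geometric mean across samples,
    computed over genes that are positive in every sample; the factor for a
    sample is the median ratio of its counts to that reference.
    """
    data = counts.data if isinstance(counts, OmicsMatrix) else counts
    values = data.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene is positive in all samples; prefilter the matrix (e.g. filter_expression) first"
        )
    ref = values[positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(factors, index=data.columns, name="size_factor")


def rle_normalize(counts: OmicsMatrix | pd.DataFrame) -> pd.DataFrame:
    data = counts.data if isinstance(counts, OmicsMatrix) else counts
    return data / rle_size_factors(counts)


# ---------------------------------------------------------------------------
# Clock preprocessing and prediction
# ---------------------------------------------------------------------------

def preprocess_for_clock(
    counts: OmicsMatrix,
    clock: ClockModel,
    sample_sheet: pd.DataFrame,
    reference_groups: tuple[str, ...] | str = ("YY", "YO"),
    reference_role: str = "before",
) -> ProcessedMatrix:
    """Run the five-step clock preprocessing pipeline.

    Steps, in order: RLE normalization; log2(x+1); per-feature z-scaling
    across samples (zero-variance features are left at 0); injection of clock
    features absent from the data as constant rows at their stored imputation
    means; centering to the per-feature median of the reference samples.
    The default reference is young donor tissue before transplantation: the
    'before' samples of the groups with a young donor (YY and YO).
    """
    if isinstance(reference_groups, str):
        reference_groups = (reference_groups,)
    ref_mask = sample_sheet["group"].isin(reference_groups) & (
        sample_sheet["role"] == reference_role
    )
    ref_samples = sample_sheet.loc[ref_mask, "sample_id"].tolist()
    ref_samples = [s for s in ref_samples if s in counts.data.columns]
    if not ref_samples:
        raise ValueError(
            f"reference groups {reference_groups!r} role {reference_role!r} have no samples in the matrix"
        )

    normalized = rle_normalize(counts)
    logged = np.log2(normalized + 1.0)

    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    scaled = logged.sub(mean, axis=0)
    nonzero = sd > 0
    scaled.loc[nonzero] = scaled.loc[nonzero].div(sd[nonzero], axis=0)
    scaled.loc[~nonzero] = 0.0

    missing = [f for f in clock.features if f not in scaled.index]
    if missing:
        imput = clock.imputation_series()
        fill = pd.DataFrame(
            np.tile(imput.loc[missing].to_numpy()[:, None], (1, scaled.shape[1])),
            index=missing,
            columns=scaled.columns,
        )
        scaled = pd.concat([scaled, fill])

    ref_median = scaled[ref_samples].median(axis=1)
    centered = scaled.sub(ref_median, axis=0)

    return ProcessedMatrix(
        data=centered,
        steps=list(PREPROCESS_STEPS),
        reference_group="+".join(reference_groups) + f":{reference_role}",
    )


def predict_age(clock: ClockModel, processed: ProcessedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Apply a linear clock: value = intercept + sum_i coef_i * x_i per sample.

    Returns a DataFrame with columns ``sample_id, prediction, sd, clock`` in
    the clock's target units (age for chronological clocks, log-hazard for
    mortality clocks).
    """
    data = processed.data if isinstance(processed, ProcessedMatrix) else processed
    missing = [f for f in clock.features if f not in data.index]
    if missing:
        raise KeyError(
            f"clock {clock.name!r} features missing from matrix (run preprocess_for_clock "
            f"or impute_features first): {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    x = data.loc[clock.features].to_numpy(dtype=float)
    values = clock.intercept + clock.coefficients @ x
    return pd.DataFrame(
        {
            "sample_id": data.columns,
            "prediction": values,
            "sd": clock.sd,
            "clock": clock.name,
        }
    )


def impute_features(matrix: pd.DataFrame, clock: ClockModel) -> pd.DataFrame:
    """Add clock features missing from ``matrix`` as constant rows at their
    stored imputation means (used for methylation matrices, which skip the
    expression preprocessing pipeline)."""
    missing = [f for f in clock.features if f not in matrix.index]
    if not missing:
        return matrix
    imput = clock.imputation_series()
    fill = pd.DataFrame(
        np.tile(imput.loc[missing].to_numpy()[:, None], (1, matrix.shape[1])),
        index=missing,
        columns=matrix.columns,
    )
    return pd.concat([matrix, fill])


def standardize_within_group(
    predictions: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    allow_constant: bool = False,
) -> pd.DataFrame:
    """Z-score predictions within each experimental group (sd with n-1).

    Used for module-specific clocks, whose outputs are standardized within
    each group before Before/After comparison. Groups of size 1 raise; a
    constant group raises unless ``allow_constant`` (then zeros).
    """
    merged = predictions.merge(
        sample_sheet[["sample_id", "group"]], on="sample_id", how="left", validate="one_to_one"
    )
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples absent from sample sheet: {missing}")
    out = merged.copy()
    out["z"] = np.nan
    for group, idx in merged.groupby("group").groups.items():
        vals = merged.loc[idx, "prediction"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples; cannot standardize")
        sd = vals.std(ddof=1)
        if sd == 0:
            if not allow_constant:
                raise ValueError(f"group {group!r} has constant predictions; cannot standardize")
            out.loc[idx, "z"] = 0.0
        else:
            out.loc[idx, "z"] = (vals - vals.mean()) / sd
    return out
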