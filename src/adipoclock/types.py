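"""Shared domain types for the adipose-transplant clock pipeline.

Conventions used throughout the package:

* Omics matrices are features x samples :class:`pandas.DataFrame` objects
  (feature IDs as the index, sample IDs as columns), wrapped in
  :class:`OmicsMatrix` with a modality tag.
* Sample sheets are DataFrames with columns
  ``sample_id, donor_id, group, role, age_months, batch`` where
  ``group`` is one of ``YY, YO, OY, OO, SHAM`` (donor-to-host) and ``role``
  is one of ``before, after, native, sham``.
* Clock models are sparse linear predictors over named features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Transplant groups, donor-to-host: young-to-young, young-to-old,
#: old-to-young, old-to-old.
TRANSPLANT_GROUPS = ("YY", "YO", "OY", "OO")
SHAM_GROUP = "SHAM"
ALL_GROUPS = TRANSPLANT_GROUPS + (SHAM_GROUP,)

ROLES = ("before", "after", "native", "sham")

SAMPLE_SHEET_COLUMNS = ("sample_id", "donor_id", "group", "role", "age_months", "batch")

TARGET_SCALES = ("chronological_age", "log_hazard")


@dataclass
class ClockModel:
    """A named linear clock: value = intercept + sum_i coef_i * x_i.

    ``target`` declares the output scale: ``chronological_age`` (years or
    months, as trained) or ``log_hazard`` for mortality clocks.
    ``imputation_means`` hold the precomputed average processed value per
    feature, used to fill clock features absent from a dataset.
    ``sd`` is an optional prediction standard deviation (same units as the
    prediction) attached to every sample's prediction.
    """

    name: str
    target: str
    features: list[str]
    coefficients: np.ndarray
    intercept: float
    imputation_means: np.ndarray
    sd: float = 0.0

    def __post_init__(self) -> None:
        self.features = list(self.features)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.imputation_means = np.asarray(self.imputation_means, dtype=float)
        if self.target not in TARGET_SCALES:
            raise ValueError(f"unknown target scale {self.target!r}; expected one of {TARGET_SCALES}")
        if len(self.features) == 0:
            raise ValueError("clock must have at least one feature")
        if not (len(self.features) == len(self.coefficients) == len(self.imputation_means)):
            raise ValueError("features, coefficients and imputation_means must be keyed by the same feature set")
        if not np.isfinite(self.intercept):
            raise ValueError("clock intercept must be finite")
        if self.sd < 0:
            raise ValueError("prediction sd must be >= 0")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.features, name="coefficient")

    def imputation_series(self) -> pd.Series:
        return pd.Series(self.imputation_means, index=self.features, name="imputation_mean")


@dataclass
class OmicsMatrix:
    """Features x samples numeric matrix with a modality tag.

    ``counts`` matrices must be non-negative; ``beta`` (methylation fraction)
    matrices must lie in [0, 1].
    """

    data: pd.DataFrame
    modality: str  # 'counts' | 'beta'

    def __post_init__(self) -> None:
        if self.modality not in ("counts", "beta"):
            raise ValueError(f"unknown modality {self.modality!r}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite values")
        if self.modality == "counts" and values.size and values.min() < 0:
            raise ValueError("count matrix contains negative values")
        if self.modality == "beta" and values.size and (values.min() < 0 or values.max() > 1):
            raise ValueError("beta matrix values must lie in [0, 1]")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


@dataclass
class ProcessedMatrix:
    """Clock-ready expression matrix plus the provenance of how it was made."""

    data: pd.DataFrame
    steps: list[str] = field(default_factory=list)
    reference_group: str | None = None


@dataclass
class ContrastResult:
    """One estimated model term in one comparison."""

    term: str
    estimate: float
    se: float
    p: float
    p_adj: float | None = None
    model: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class ShamCalibration:
    """OLS map from chronological age to predicted (clock) age on shams."""

    slope: float
    intercept: float
    n: int
    residual_sd: float
    intercept_only: bool = False

    def expected(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet for the required columns and value domains."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad_groups = set(sheet["group"]) - set(ALL_GROUPS)
    if bad_groups:
        raise ValueError(f"unknown groups in sample sheet: {sorted(bad_groups)}")
    bad_roles = set(sheet["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles in sample sheet: {sorted(bad_roles)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    return sheet
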