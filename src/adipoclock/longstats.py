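"""Longitudinal statistics for the transplant design.

Within-group Before/After/Native comparisons are fit as ordinary least
squares with the tissue role and the donor ID as categorical fixed effects
(the donor term makes the role contrast a paired, within-animal comparison).
Between-group comparisons of Before->After dynamics use the stage x group
interaction term. Clock predictions that carry a per-sample uncertainty are
compared with a single-random-intercept mixed model in which the stated
prediction sd enters as a known per-observation measurement variance added
to the residual variance; the two free variance components (donor, residual)
are estimated by REML.

Multiple-testing adjustment is Benjamini-Hochberg, applied over an explicit
family of p-values supplied by the caller -- never implicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import ContrastResult, ShamCalibration

__all__ = [
    "paired_contrast",
    "interaction_contrast",
    "weighted_mixed_contrast",
    "sham_calibrate",
    "age_deviation",
    "bh_adjust",
    "adjust_family",
]


# ---------------------------------------------------------------------------
# OLS helpers
# ---------------------------------------------------------------------------

def _dummies(labels: np.ndarray, drop_first: bool = True) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(labels))
    used = levels[1:] if drop_first else levels
    cols = np.column_stack([(labels == lv).astype(float) for lv in used]) if used else np.empty((len(labels), 0))
    return cols, [str(lv) for lv in used]


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> dict:
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {k} columns); "
            "the factors are confounded"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals = np.where(se > 0, pvals, 0.0)
    return {"beta": beta, "se": se, "p": pvals, "names": names, "df": df, "n": n, "sigma2": sigma2}


def _align(values: pd.Series, sheet: pd.DataFrame) -> pd.DataFrame:
    df = sheet.copy()
    df = df[df["sample_id"].isin(values.index)]
    df["y"] = values.loc[df["sample_id"]].to_numpy(dtype=float)
    return df


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def paired_contrast(
    values: pd.Series,
    sample_sheet: pd.DataFrame,
    reference_role: str = "before",
) -> list[ContrastResult]:
    """Within-group role contrasts with the donor as a paired covariate.

    Fits ``y ~ C(role) + C(donor)`` on the provided samples (typically one
    experimental group) and reports one :class:`ContrastResult` per
    non-reference role, e.g. the After-Before paired effect. ``values`` is a
    Series indexed by sample_id.
    """
    df = _align(values, sample_sheet)
    roles = list(pd.unique(df["role"]))
    if len(roles) < 2:
        raise ValueError(f"need >= 2 tissue roles, got {roles}")
    if reference_role not in roles:
        raise ValueError(f"reference role {reference_role!r} absent from data")
    other = sorted(r for r in roles if r != reference_role)
    role_cols = np.column_stack([(df["role"].to_numpy() == r).astype(float) for r in other])
    donor_cols, _ = _dummies(df["donor_id"].to_numpy())
    X = np.column_stack([np.ones(len(df)), role_cols, donor_cols])
    names = ["intercept"] + [f"role[{r}]" for r in other] + ["donor"] * donor_cols.shape[1]
    fit = _ols(X, df["y"].to_numpy(), names)
    model = f"y ~ role + donor (OLS, ref={reference_role})"
    out = []
    for j, r in enumerate(other, start=1):
        out.append(
            ContrastResult(
                term=f"role[{r}]",
                estimate=float(fit["beta"][j]),
                se=float(fit["se"][j]),
                p=float(fit["p"][j]),
                model=model,
                n=fit["n"],
            )
        )
    return out


def interaction_contrast(
    values: pd.Series,
    sample_sheet: pd.DataFrame,
    groups: tuple[str, str],
    stages: tuple[str, str] = ("before", "after"),
) -> ContrastResult:
    """Stage x group interaction: difference in Before->After dynamics.

    Fits ``y ~ stage + group + stage:group`` on the before/after samples of
    the two groups and returns the interaction coefficient, i.e. the second
    group's Before->After change minus the first group's.
    """
    df = _align(values, sample_sheet)
    df = df[df["group"].isin(groups) & df["role"].isin(stages)]
    for g in groups:
        present = set(df.loc[df["group"] == g, "role"])
        if set(stages) - present:
            raise ValueError(f"group {g!r} is missing stage(s) {sorted(set(stages) - present)}")
    stage_ind = (df["role"].to_numpy() == stages[1]).astype(float)
    group_ind = (df["group"].to_numpy() == groups[1]).astype(float)
    X = np.column_stack([np.ones(len(df)), stage_ind, group_ind, stage_ind * group_ind])
    fit = _ols(X, df["y"].to_numpy(), ["intercept", "stage", "group", "stage:group"])
    return ContrastResult(
        term=f"stage:group[{groups[1]}-{groups[0]}]",
        estimate=float(fit["beta"][3]),
        se=float(fit["se"][3]),
        p=float(fit["p"][3]),
        model="y ~ stage * group (OLS)",
        n=fit["n"],
    )


# ---------------------------------------------------------------------------
# Measurement-error mixed model (single random intercept, REML)
# ---------------------------------------------------------------------------

def _reml_neg_loglik(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    donor_idx: np.ndarray,
    n_donors: int,
    meas_var: np.ndarray,
) -> float:
    sd2, sr2 = np.exp(theta)
    v_diag = sr2 + meas_var
    # V = diag(v_diag) + sd2 * Z Z'; use Woodbury via per-donor blocks.
    Vinv_y = np.empty_like(y)
    Vinv_X = np.empty_like(X)
    logdet = 0.0
    for d in range(n_donors):
        m = donor_idx == d
        vd = v_diag[m]
        inv_d = 1.0 / vd
        s = inv_d.sum()
        c = sd2 / (1.0 + sd2 * s)
        logdet += np.log(vd).sum() + np.log1p(sd2 * s)
        yy = y[m]
        Vinv_y[m] = inv_d * yy - inv_d * c * (inv_d @ yy)
        Xd = X[m]
        Vinv_X[m] = inv_d[:, None] * Xd - np.outer(inv_d * c, inv_d @ Xd)
    XtVinvX = X.T @ Vinv_X
    try:
        cf = np.linalg.cholesky(XtVinvX)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    r = y - X @ beta
    # r' V^-1 r = r' Vinv_y - r' Vinv_X beta  (since Vinv symmetric)
    quad = float(r @ (Vinv_y - Vinv_X @ beta))
    logdet_XtVX = 2.0 * np.log(np.diag(cf)).sum()
    return 0.5 * (logdet + logdet_XtVX + quad)


def weighted_mixed_contrast(
    values: pd.Series,
    sample_sheet: pd.DataFrame,
    prediction_sd: pd.Series | float,
    focal: str = "role[after]",
    reference_role: str = "before",
    include_batch: bool = True,
) -> ContrastResult:
    """Role contrast under a random donor intercept with known per-observation
    measurement variance.

    Model: y = X beta + b_donor + e, b ~ N(0, sd^2), e_i ~ N(0, sr^2 + s_i^2)
    where s_i is the supplied prediction sd. Fixed effects: intercept, role
    dummies, and (optionally) batch dummies. sd^2 and sr^2 are estimated by
    REML; inference on the focal fixed effect uses the GLS standard error with
    a t reference on n - p degrees of freedom.
    """
    df = _align(values, sample_sheet)
    if df["donor_id"].nunique() < 2:
        raise ValueError("need >= 2 donors for the mixed model")
    if np.isscalar(prediction_sd):
        s = np.full(len(df), float(prediction_sd))
    else:
        s = prediction_sd.loc[df["sample_id"]].to_numpy(dtype=float)
    if (s < 0).any():
        raise ValueError("prediction sds must be >= 0")
    roles = sorted(r for r in pd.unique(df["role"]) if r != reference_role)
    cols = [np.ones(len(df))] + [(df["role"].to_numpy() == r).astype(float) for r in roles]
    names = ["intercept"] + [f"role[{r}]" for r in roles]
    if include_batch and df["batch"].nunique() > 1:
        bcols, blevels = _dummies(df["batch"].to_numpy())
        cols.append(bcols)
        names += [f"batch[{b}]" for b in blevels]
        X = np.column_stack([np.column_stack(cols[:-1]), bcols])
    else:
        X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")

    donors = pd.unique(df["donor_id"])
    donor_idx = pd.Categorical(df["donor_id"], categories=donors).codes.astype(int)
    y = df["y"].to_numpy(dtype=float)

    var_y = max(y.var(ddof=1), 1e-8)
    best = None
    for start in ([np.log(var_y / 2)] * 2, [np.log(var_y / 10), np.log(var_y)], [-8.0, np.log(var_y)]):
        res = optimize.minimize(
            _reml_neg_loglik,
            np.asarray(start, dtype=float),
            args=(y, X, donor_idx, len(donors), s**2),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"mixed-model REML did not converge: {best}")
    sd2, sr2 = np.exp(best.x)

    # GLS at the REML variance components
    v_diag = sr2 + s**2
    n = len(y)
    V = np.diag(v_diag)
    Z = np.zeros((n, len(donors)))
    Z[np.arange(n), donor_idx] = 1.0
    V += sd2 * Z @ Z.T
    Vinv = np.linalg.inv(V)
    XtVinvX_inv = np.linalg.inv(X.T @ Vinv @ X)
    beta = XtVinvX_inv @ X.T @ Vinv @ y
    se = np.sqrt(np.diag(XtVinvX_inv))
    dfree = n - X.shape[1]
    if focal not in names:
        raise ValueError(f"focal term {focal!r} not in fixed effects {names}")
    j = names.index(focal)
    t = beta[j] / se[j] if se[j] > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), dfree))
    return ContrastResult(
        term=focal,
        estimate=float(beta[j]),
        se=float(se[j]),
        p=p,
        model=(
            f"y ~ role{' + batch' if include_batch else ''} + (1|donor), REML, "
            f"known meas. var; sigma2_donor={sd2:.4g}, sigma2_res={sr2:.4g}"
        ),
        n=n,
    )


def mixed_variance_components(
    values: pd.Series,
    sample_sheet: pd.DataFrame,
    prediction_sd: pd.Series | float = 0.0,
    reference_role: str = "before",
) -> tuple[float, float]:
    """REML donor and residual variance estimates from the mixed model above."""
    df = _align(values, sample_sheet)
    if np.isscalar(prediction_sd):
        s = np.full(len(df), float(prediction_sd))
    else:
        s = prediction_sd.loc[df["sample_id"]].to_numpy(dtype=float)
    roles = sorted(r for r in pd.unique(df["role"]) if r != reference_role)
    X = np.column_stack([np.ones(len(df))] + [(df["role"].to_numpy() == r).astype(float) for r in roles])
    donors = pd.unique(df["donor_id"])
    donor_idx = pd.Categorical(df["donor_id"], categories=donors).codes.astype(int)
    y = df["y"].to_numpy(dtype=float)
    var_y = max(y.var(ddof=1), 1e-8)
    best = None
    for start in ([np.log(var_y / 2)] * 2, [np.log(var_y), np.log(var_y / 10)]):
        res = optimize.minimize(
            _reml_neg_loglik,
            np.asarray(start, dtype=float),
            args=(y, X, donor_idx, len(donors), s**2),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    sd2, sr2 = np.exp(best.x)
    return float(sd2), float(sr2)


# ---------------------------------------------------------------------------
# Sham calibration
# ---------------------------------------------------------------------------

def sham_calibrate(ages: np.ndarray, predictions: np.ndarray) -> ShamCalibration:
    """OLS fit of predicted age on chronological age over sham samples.

    With fewer than two distinct ages the fit degenerates to an
    intercept-only model (mean prediction), flagged on the result.
    """
    ages = np.asarray(ages, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if ages.size == 0:
        raise ValueError("no sham samples: cannot calibrate")
    if ages.shape != predictions.shape:
        raise ValueError("ages and predictions differ in length")
    if np.unique(ages).size < 2 or ages.size < 2:
        resid = predictions - predictions.mean()
        rsd = float(resid.std(ddof=1)) if ages.size > 1 else 0.0
        return ShamCalibration(
            slope=0.0, intercept=float(predictions.mean()), n=int(ages.size),
            residual_sd=rsd, intercept_only=True,
        )
    slope, intercept = np.polyfit(ages, predictions, 1)
    resid = predictions - (intercept + slope * ages)
    dof = max(ages.size - 2, 1)
    return ShamCalibration(
        slope=float(slope),
        intercept=float(intercept),
        n=int(ages.size),
        residual_sd=float(np.sqrt((resid @ resid) / dof)),
    )


def age_deviation(
    calibration: ShamCalibration,
    ages: np.ndarray | float,
    predictions: np.ndarray | float,
):
    """Observed minus expected prediction: pred - (intercept + slope*age)."""
    return np.asarray(predictions, dtype=float) - calibration.expected(ages)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_(i) -> min_{j>=i} ( m * p_(j) / j ), capped at 1; ties share a value.
    The family is exactly the vector passed in.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def adjust_family(results: list[ContrastResult]) -> list[ContrastResult]:
    """Fill ``p_adj`` by BH over the given results, treated as one family."""
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results
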