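"""Differential change analysis and clock deconvolution.

The Before->After expression response within a group is fit per gene as a
paired linear model on log2-CPM (counts per million after RLE size factors,
+0.5 pseudocount) with the transplantation stage and the donor ID as
covariates. Clock deconvolution decomposes the predicted age change between
mean Before and mean After profiles into additive per-gene contributions
(processed-scale change x clock coefficient); because the clock is linear,
the contributions sum to the predicted mean-profile difference exactly.

The screen for age-dynamics-associated genes regresses each gene's
expression on the per-donor predicted-age change (attributed to After
samples) with stage and donor covariates, adjusts with BH, and reports the
q < 0.05 set. Pathway over-representation uses the one-sided hypergeometric
(Fisher) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clockcore import rle_size_factors
from .longstats import bh_adjust
from .types import ClockModel, OmicsMatrix, ProcessedMatrix

__all__ = [
    "log2_cpm",
    "paired_de",
    "gene_contributions",
    "ranking_metric",
    "tage_association_screen",
    "fisher_enrichment",
    "correlation_compare",
]


def log2_cpm(counts: OmicsMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million after RLE size-factor normalization.

    The RLE factors already carry the per-sample scaling, so the
    per-million rescaling uses one common divisor (the median normalized
    library size) rather than per-sample totals -- dividing by per-sample
    totals again would renormalize twice and shrink genuine fold changes.
    """
    norm = counts.data / rle_size_factors(counts)
    lib = float(np.median(norm.sum(axis=0)))
    return np.log2((norm + pseudocount) / lib * 1e6)


def _genewise_ols(Y: np.ndarray, X: np.ndarray, focal_col: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene OLS of Y (genes x samples) on shared design X.

    Returns (estimate, se, p) for the focal column.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient; covariates are collinear")
    df = n - k
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # k x n
    B = Y @ H.T  # genes x k
    resid = Y - B @ X.T
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[focal_col, focal_col], 0.0))
    est = B[:, focal_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / se, np.inf * np.sign(est))
    p = 2.0 * stats.t.sf(np.abs(tvals), df)
    p = np.where(se > 0, p, np.where(est == 0, 1.0, 0.0))
    return est, se, p


def paired_de(
    counts: OmicsMatrix,
    sample_sheet: pd.DataFrame,
    group: str,
    stages: tuple[str, str] = ("before", "after"),
) -> pd.DataFrame:
    """Per-gene paired Before->After differential expression for one group.

    Fits log2-CPM ~ stage + donor; logFC is the stage coefficient
    (log2 units), p from the t-test on that coefficient, q by BH across
    genes. Returns a DataFrame indexed by gene with columns
    ``logFC, p, q``.
    """
    sub = sample_sheet[
        (sample_sheet["group"] == group) & sample_sheet["role"].isin(stages)
    ]
    sub = sub[sub["sample_id"].isin(counts.data.columns)]
    donors = sub.groupby("donor_id")["role"].nunique()
    if (donors >= 2).sum() < 2:
        raise ValueError(
            f"group {group!r} needs >= 2 donors with both stages; found {(donors >= 2).sum()}"
        )
    expr = log2_cpm(OmicsMatrix(counts.data[sub["sample_id"].tolist()], "counts"))
    stage = (sub["role"].to_numpy() == stages[1]).astype(float)
    donor_levels = list(pd.unique(sub["donor_id"]))[1:]
    donor_cols = np.column_stack(
        [(sub["donor_id"].to_numpy() == d).astype(float) for d in donor_levels]
    ) if donor_levels else np.empty((len(sub), 0))
    X = np.column_stack([np.ones(len(sub)), stage, donor_cols])
    est, se, p = _genewise_ols(expr.to_numpy(), X, focal_col=1)
    return pd.DataFrame({"logFC": est, "se": se, "p": p, "q": bh_adjust(p)}, index=expr.index)


# ---------------------------------------------------------------------------
# Clock deconvolution
# ---------------------------------------------------------------------------

@dataclass
class ContributionResult:
    table: pd.DataFrame  # gene, delta, coefficient, contribution
    total: float  # predicted mean-profile difference (clock units)


def gene_contributions(
    processed: ProcessedMatrix,
    sample_sheet: pd.DataFrame,
    clock: ClockModel,
    group: str | None = None,
    stages: tuple[str, str] = ("before", "after"),
    de_logfc: pd.Series | None = None,
) -> ContributionResult:
    """Per-gene contributions to the clock-predicted Before->After change.

    delta_i = mean(After) - mean(Before) of processed feature i;
    contribution_i = coef_i * delta_i. By linearity the contributions sum to
    the clock prediction of the mean After profile minus that of the mean
    Before profile exactly. Passing ``de_logfc`` substitutes the DE-model
    logFC for delta (the conservation identity then no longer holds).
    """
    sheet = sample_sheet
    if group is not None:
        sheet = sheet[sheet["group"] == group]
    before = sheet.loc[sheet["role"] == stages[0], "sample_id"]
    after = sheet.loc[sheet["role"] == stages[1], "sample_id"]
    before = [s for s in before if s in processed.data.columns]
    after = [s for s in after if s in processed.data.columns]
    if not before or not after:
        raise ValueError(f"need both {stages[0]!r} and {stages[1]!r} samples")
    missing = [f for f in clock.features if f not in processed.data.index]
    if missing:
        raise KeyError(f"clock features missing from processed matrix: {missing[:5]}")
    sub = processed.data.loc[clock.features]
    delta = sub[after].mean(axis=1) - sub[before].mean(axis=1)
    if de_logfc is not None:
        delta = de_logfc.reindex(clock.features)
        if delta.isna().any():
            raise ValueError("de_logfc does not cover all clock features")
    coef = clock.coef_series()
    contrib = coef * delta
    table = pd.DataFrame(
        {"delta": delta, "coefficient": coef, "contribution": contrib}
    )
    return ContributionResult(table=table, total=float(contrib.sum()))


def ranking_metric(p: np.ndarray, lfc: np.ndarray, base: float = np.e) -> np.ndarray:
    """Signed significance score -log(p) * sgn(lfc) (natural log by default)."""
    p = np.asarray(p, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive double", stacklevel=2)
        p = np.where(p == 0, np.finfo(float).tiny, p)
    return -np.log(p) / np.log(base) * np.sign(lfc)


# ---------------------------------------------------------------------------
# tAge-association screen
# ---------------------------------------------------------------------------

def tage_association_screen(
    values: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    dtage: pd.Series,
    stages: tuple[str, str] = ("before", "after"),
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen genes whose expression tracks the predicted-age change.

    ``values`` is genes x samples expression (any log-scale matrix);
    ``dtage`` maps donor_id -> predicted-age change for that donor. Each
    After sample carries its donor's change as the covariate (Before samples
    carry 0), alongside stage and donor covariates. Returns per-gene
    ``estimate, se, p, q, significant``, sorted by (q, -|estimate|, gene).
    """
    sub = sample_sheet[sample_sheet["role"].isin(stages)]
    sub = sub[sub["sample_id"].isin(values.columns)]
    after_mask = (sub["role"] == stages[1]).to_numpy()
    missing = set(sub.loc[after_mask, "donor_id"]) - set(dtage.index)
    if missing:
        raise ValueError(f"dtage missing for donors: {sorted(missing)[:5]}")
    x = np.where(after_mask, sub["donor_id"].map(dtage).to_numpy(dtype=float), 0.0)
    stage = after_mask.astype(float)
    donor_levels = list(pd.unique(sub["donor_id"]))[1:]
    donor_cols = np.column_stack(
        [(sub["donor_id"].to_numpy() == d).astype(float) for d in donor_levels]
    ) if donor_levels else np.empty((len(sub), 0))
    X = np.column_stack([np.ones(len(sub)), x, stage, donor_cols])
    Y = values[sub["sample_id"].tolist()].to_numpy()
    est, se, p = _genewise_ols(Y, X, focal_col=1)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {"estimate": est, "se": se, "p": p, "q": q, "significant": q < q_threshold},
        index=values.index,
    )
    out["gene"] = out.index
    out = out.sort_values(["q", "estimate", "gene"], key=lambda col: -col.abs() if col.name == "estimate" else col)
    return out.drop(columns="gene")


# ---------------------------------------------------------------------------
# Enrichment and correlation
# ---------------------------------------------------------------------------

def fisher_enrichment(
    hits: set[str],
    universe: set[str],
    pathways: dict[str, set[str]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test per pathway (hypergeometric tail).

    ``hits`` must be a subset of ``universe``; pathway members outside the
    universe are ignored. Returns per-pathway ``k, K, odds_ratio, p, q,
    significant`` sorted by (q, pathway).
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name in sorted(pathways):
        members = set(pathways[name]) & universe
        K = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((name, k, K, odds, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway", "k", "K", "odds_ratio", "p"]).set_index("pathway")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < q_threshold
    return out


def correlation_compare(vectors: dict[str, pd.Series]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of named gene-level vectors.

    Vectors are inner-joined on their index; fewer than 3 shared entries is
    an error. Returns (R, p, q) matrices; the diagonal has R=1 and p
    reported as 0 (degenerate self-comparison). BH is applied over the
    strictly-upper-triangle family.
    """
    names = list(vectors)
    joined = pd.concat({k: v for k, v in vectors.items()}, axis=1, join="inner")
    if joined.shape[0] < 3:
        raise ValueError(f"only {joined.shape[0]} shared genes; need >= 3")
    m = len(names)
    R = pd.DataFrame(np.eye(m), index=names, columns=names)
    P = pd.DataFrame(np.zeros((m, m)), index=names, columns=names)
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            r, p = stats.pearsonr(joined[names[i]], joined[names[j]])
            R.iloc[i, j] = R.iloc[j, i] = r
            P.iloc[i, j] = P.iloc[j, i] = p
            pairs.append(p)
    Q = pd.DataFrame(np.zeros((m, m)), index=names, columns=names)
    if pairs:
        qv = bh_adjust(pairs)
        idx = 0
        for i in range(m):
            for j in range(i + 1, m):
                Q.iloc[i, j] = Q.iloc[j, i] = qv[idx]
                idx += 1
    return R, P, Q
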