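"""Synthetic data generators emulating the transplant study design.

The generators produce every input the downstream stages consume -- sample
sheets for the four-group transplant design plus sham controls, sparse linear
clocks, bulk RNA-seq count matrices with negative-binomial noise and a
planted clock-age signal, methylation beta matrices with detection p-values,
H&E-like adipose sections, and labeled 3D mitochondria volumes -- together
with the ground truth needed to test recovery.

Clock-signal planting for expression works backwards from the preprocessing
pipeline. The pipeline z-scales every feature across samples, which pins each
processed clock-feature row to mean 0 / sd 1; an arbitrary target-age
trajectory t_s is therefore representable only through its standardized shape
u_s = (t_s - mean t)/sd(t), with total amplitude bounded by the sum of
absolute clock coefficients. The generator splits the clock features into two
sum-balanced sets and writes sign(c_i) * (cos(theta_g) u + sin(theta_g) w)
into each feature (w an orthonormal nuisance direction), choosing the two
angles so the coefficient-weighted sum is exactly sd(t) * u: the planted
Before->After differences and group shifts survive preprocessing exactly, up
to count rounding. The analytically achieved per-sample prediction (which
includes a common additive offset fixed by the clock intercept and the
reference-median centering) is recorded as the truth.

All randomness flows from a single integer seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ALL_GROUPS,
    SHAM_GROUP,
    TRANSPLANT_GROUPS,
    ClockModel,
    OmicsMatrix,
)

# H&E-like rendering palette (8-bit RGB). Chosen so each class satisfies
# exactly one of the downstream classification rules:
#   droplet  -> all channels >= 190 (and min >= 235: counts as white space)
#   nucleus  -> R <= 150, G <= 150, B <= 200
#   collagen -> R in [170,220], G in [190,240], B in [210,255], R < 190
#   tissue   -> none of the above
DROPLET_RGB = (245, 245, 245)
NUCLEUS_RGB = (120, 60, 160)
COLLAGEN_RGB = (175, 195, 240)
TISSUE_RGB = (230, 180, 190)

MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class DesignSpec:
    """Parameters of the transplant experiment to simulate.

    Ages are months; the follow-up interval is the 10-week post-transplant
    window. The graft mass is normalized to 1% of recipient body weight in
    the experiment the design emulates; it is carried in the sheet-level
    metadata for provenance but does not influence the simulation.
    """

    donors_per_group: int = 8
    n_sham: int = 6
    young_age: float = 4.0
    old_age: float = 18.0
    followup_months: float = 2.3
    graft_mass_fraction: float = 0.01
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donors_per_group < 1:
            raise ValueError("donors_per_group must be >= 1 for every transplant group")
        if self.n_sham < 0:
            raise ValueError("n_sham must be >= 0")
        if not self.young_age < self.old_age:
            raise ValueError("young_age must be < old_age")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    seed: int
    sample_targets: pd.DataFrame | None = None  # sample_id, target_raw, true_signal
    group_shifts: dict = field(default_factory=dict)
    gene_lfc: pd.Series | None = None
    donor_changes: pd.Series | None = None  # per-donor planted clock change
    objects: pd.DataFrame | None = None  # rendered image / volume object table


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Emit the sample sheet for the 4-group transplant design + shams.

    Each transplant donor contributes a Before and an After record for the
    graft and a Native record for the recipient's untouched tissue; each sham
    animal contributes one record per time point. Batches are assigned
    round-robin over records.
    """
    records = []
    for group in TRANSPLANT_GROUPS:
        donor_age = spec.young_age if group[0] == "Y" else spec.old_age
        host_age = spec.young_age if group[1] == "Y" else spec.old_age
        for d in range(1, spec.donors_per_group + 1):
            donor = f"{group}_d{d}"
            records.append((f"{donor}_before", donor, group, "before", donor_age))
            records.append((f"{donor}_after", donor, group, "after", donor_age + spec.followup_months))
            records.append((f"{donor}_native", donor, group, "native", host_age + spec.followup_months))
    for d in range(1, spec.n_sham + 1):
        age = spec.young_age if d % 2 == 1 else spec.old_age
        donor = f"{SHAM_GROUP}_d{d}"
        records.append((f"{donor}_t0", donor, SHAM_GROUP, "sham", age))
        records.append((f"{donor}_t1", donor, SHAM_GROUP, "sham", age + spec.followup_months))
    sheet = pd.DataFrame(records, columns=["sample_id", "donor_id", "group", "role", "age_months"])
    sheet["batch"] = [f"b{i % spec.n_batches + 1}" for i in range(len(sheet))]
    sheet.attrs["graft_mass_fraction"] = spec.graft_mass_fraction
    return sheet


# ---------------------------------------------------------------------------
# Clocks
# ---------------------------------------------------------------------------

def generate_linear_clock(
    n_features: int,
    density: float = 1.0,
    coef_scale: float = 1.0,
    intercept: float = 0.0,
    target: str = "chronological_age",
    seed: int = 0,
    feature_prefix: str = "G",
    name: str | None = None,
) -> ClockModel:
    """Random sparse linear clock over ``n_features`` named features.

    Exactly ``round(density * n_features)`` coefficients are nonzero, drawn
    N(0, coef_scale^2); the rest are exactly 0. Imputation means are drawn
    N(0, 0.1^2) on the processed-expression scale.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    features = [f"{feature_prefix}{i:05d}" for i in range(n_features)]
    k = int(round(density * n_features))
    k = max(k, 1) if density > 0 else 0
    coefs = np.zeros(n_features)
    nz = rng.choice(n_features, size=k, replace=False)
    coefs[nz] = rng.normal(0.0, coef_scale, size=k) if coef_scale > 0 else 0.0
    means = rng.normal(0.0, 0.1, size=n_features)
    return ClockModel(
        name=name or f"synthetic-{target}-{seed}",
        target=target,
        features=features,
        coefficients=coefs,
        intercept=float(intercept),
        imputation_means=means,
        sd=0.0,
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _target_trajectory(
    sheet: pd.DataFrame, age_slope: float, group_shifts: dict[str, float]
) -> np.ndarray:
    shifts = {g: 0.0 for g in ALL_GROUPS}
    shifts.update(group_shifts or {})
    for g, v in shifts.items():
        if not np.isfinite(v):
            raise ValueError(f"group shift for {g!r} must be finite")
    t = age_slope * sheet["age_months"].to_numpy(dtype=float)
    after = (sheet["role"] == "after").to_numpy()
    t = t + np.where(after, sheet["group"].map(shifts).to_numpy(dtype=float), 0.0)
    return t


def _balanced_partition(weights: np.ndarray) -> np.ndarray:
    """Greedy two-way partition of positive weights by descending size.

    Returns a boolean mask for set A; |sum(A) - sum(B)| <= max(weights).
    """
    order = np.argsort(weights)[::-1]
    in_a = np.zeros(len(weights), dtype=bool)
    sa = sb = 0.0
    for i in order:
        if sa <= sb:
            in_a[i] = True
            sa += weights[i]
        else:
            sb += weights[i]
    return in_a


def _plant_processed_signal(
    clock: ClockModel, u: np.ndarray, w: np.ndarray, sigma_t: float
) -> np.ndarray:
    """Processed-scale rows (k x n) for the clock's nonzero-coefficient
    features such that coefficients @ rows == sigma_t * u exactly, with every
    row mean-0 / sd-1 (ddof 0) so z-scaling is the identity on them."""
    c = clock.coefficients[clock.coefficients != 0]
    mags = np.abs(c)
    S = mags.sum()
    if sigma_t == 0.0:
        return np.zeros((len(c), len(u)))
    if sigma_t > S + 1e-12:
        raise ValueError(
            f"requested signal amplitude {sigma_t:.4g} exceeds the clock's total "
            f"coefficient weight {S:.4g}; increase coef_scale or clock density"
        )
    in_a = _balanced_partition(mags)
    sa, sb = mags[in_a].sum(), mags[~in_a].sum()
    if sigma_t < abs(sa - sb) - 1e-12:
        # shrink the heavier side by deactivating its smallest members
        heavy = in_a if sa > sb else ~in_a
        idx = np.where(heavy)[0]
        idx = idx[np.argsort(mags[idx])]
        active = np.ones(len(c), dtype=bool)
        for i in idx:
            if abs(mags[active & in_a].sum() - mags[active & ~in_a].sum()) <= sigma_t:
                break
            active[i] = False
        sa, sb = mags[active & in_a].sum(), mags[active & ~in_a].sum()
        if sigma_t < abs(sa - sb) - 1e-12 or sigma_t > sa + sb:
            raise ValueError(
                "cannot realize the requested signal amplitude with this clock's "
                "coefficient spectrum; adjust coef_scale, density, or the shifts"
            )
    else:
        active = np.ones(len(c), dtype=bool)
    sa = mags[active & in_a].sum()
    sb = mags[active & ~in_a].sum()
    # triangle with sides sa, sb and base sigma_t along u
    if sb == 0.0:
        cos_a, sin_a = 1.0, 0.0
        cos_b, sin_b = 1.0, 0.0
    else:
        cos_a = np.clip((sigma_t**2 + sa**2 - sb**2) / (2 * sigma_t * sa), -1.0, 1.0)
        sin_a = np.sqrt(max(0.0, 1.0 - cos_a**2))
        cos_b = (sigma_t - sa * cos_a) / sb
        sin_b = -sa * sin_a / sb
    rows = np.zeros((len(c), len(u)))
    sign = np.sign(c)
    a_mask = active & in_a
    b_mask = active & ~in_a
    rows[a_mask] = np.outer(sign[a_mask], cos_a * u + sin_a * w)
    rows[b_mask] = np.outer(sign[b_mask], cos_b * u + sin_b * w)
    return rows


def _orthonormal_nuisance(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A mean-0, sd-1 (ddof 0) vector orthogonal to u and the constant."""
    n = len(u)
    for _ in range(100):
        w = rng.normal(size=n)
        w -= w.mean()
        if u.std() > 0:
            w -= (w @ u) / (u @ u) * u
        sd = w.std(ddof=0)
        if sd > 1e-8:
            return w / sd
    raise RuntimeError("failed to construct a nuisance direction")


def simulate_expression(
    sheet: pd.DataFrame,
    clock: ClockModel,
    age_slope: float = 0.0,
    group_shifts: dict[str, float] | None = None,
    dispersion: float = 0.05,
    libsize_range: tuple[float, float] = (0.7, 1.3),
    n_genes: int = 400,
    gene_lfc: dict[str, float] | None = None,
    donor_shift_sd: float = 0.0,
    coupled_genes: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[OmicsMatrix, SimTruth]:
    """Simulate a bulk RNA-seq count matrix with a planted clock signal.

    Expected log-expression of the clock genes moves the clock prediction by
    ``age_slope * age + group_shifts[g]`` for After samples; counts are drawn
    negative binomial with Var = mu + dispersion * mu^2 (dispersion 0 gives
    deterministic rounded means). ``gene_lfc`` plants per-gene log2 fold
    changes in After samples of the transplant groups (on non-clock genes).
    ``donor_shift_sd`` adds donor-level heterogeneity (N(0, sd^2)) to each
    donor's Before->After clock shift; ``coupled_genes`` maps gene -> slope
    (log2 units per clock unit) for genes whose After-sample expression
    change is proportional to the donor's total planted clock change --
    the targets of the age-dynamics screen.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lo, hi = libsize_range
    if lo <= 0 or hi < lo:
        raise ValueError("libsize_range must be positive and ordered")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    missing = set(clock.features) - set(genes)
    if missing:
        raise ValueError(
            f"clock references {len(missing)} features beyond the {n_genes} simulated genes"
        )
    rng = np.random.default_rng(seed)
    samples = sheet["sample_id"].tolist()
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples to plant a signal")

    t = _target_trajectory(sheet, age_slope, group_shifts or {})
    after = ((sheet["role"] == "after") & sheet["group"].isin(TRANSPLANT_GROUPS)).to_numpy()
    donor_eta = pd.Series(0.0, index=pd.unique(sheet["donor_id"]))
    if donor_shift_sd > 0:
        donor_eta[:] = rng.normal(0.0, donor_shift_sd, size=len(donor_eta))
        t = t + np.where(after, sheet["donor_id"].map(donor_eta).to_numpy(), 0.0)
    tbar = t.mean()
    sigma_t = t.std(ddof=0)
    u = (t - tbar) / sigma_t if sigma_t > 0 else np.zeros(n)
    w = _orthonormal_nuisance(u, rng)

    active_features = [f for f, c in zip(clock.features, clock.coefficients) if c != 0]
    rows = _plant_processed_signal(clock, u, w, sigma_t)

    # log2 expression for every gene
    base_loc = rng.uniform(9.0, 12.0, size=n_genes)
    log2_expr = np.tile(base_loc[:, None], (1, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    # per-gene log2 amplitude of the clock genes (typical variable-gene range)
    scale = rng.uniform(1.0, 1.5, size=len(active_features))
    for j, feat in enumerate(active_features):
        log2_expr[gene_index[feat]] = base_loc[gene_index[feat]] + scale[j] * rows[j]

    lfc = pd.Series(0.0, index=genes, name="true_lfc")
    if gene_lfc:
        clash = set(gene_lfc) & set(active_features)
        if clash:
            raise ValueError(f"gene_lfc would overwrite clock signal genes: {sorted(clash)[:5]}")
        for g, v in gene_lfc.items():
            if g not in gene_index:
                raise ValueError(f"gene_lfc references unknown gene {g!r}")
            lfc[g] = float(v)
            log2_expr[gene_index[g]] = base_loc[gene_index[g]] + v * after

    # per-donor total planted Before->After clock change (group shift + eta)
    shifts_full = {g: 0.0 for g in ALL_GROUPS}
    shifts_full.update(group_shifts or {})
    donor_change = pd.Series(
        {
            d: shifts_full[grp] + donor_eta[d]
            for d, grp in sheet.drop_duplicates("donor_id").set_index("donor_id")["group"].items()
            if grp in TRANSPLANT_GROUPS
        },
        name="planted_change",
    )
    if coupled_genes:
        clash = set(coupled_genes) & (set(active_features) | set(gene_lfc or {}))
        if clash:
            raise ValueError(f"coupled_genes would overwrite other planted genes: {sorted(clash)[:5]}")
        change_per_sample = np.where(
            after, sheet["donor_id"].map(donor_change).fillna(0.0).to_numpy(), 0.0
        )
        for g, slope in coupled_genes.items():
            if g not in gene_index:
                raise ValueError(f"coupled_genes references unknown gene {g!r}")
            log2_expr[gene_index[g]] = base_loc[gene_index[g]] + slope * change_per_sample

    mean_counts = np.maximum(2.0**log2_expr - 1.0, 0.0)
    # relative library sizes, geometric mean fixed to 1 so RLE inverts exactly;
    # the deterministic dispersion=0 limit keeps library sizes at 1 so count
    # rounding cannot inject variance into otherwise-constant genes (which
    # per-feature z-scaling would amplify)
    if dispersion == 0.0:
        counts = np.rint(mean_counts)
        mu = mean_counts
    else:
        f = rng.uniform(lo, hi, size=n)
        f = f / np.exp(np.mean(np.log(f)))
        mu = mean_counts * f
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam).astype(float)

    matrix = OmicsMatrix(pd.DataFrame(counts, index=genes, columns=samples), "counts")

    # analytic truth: prediction after preprocessing with the default
    # young-donor-before reference
    ref = (
        sheet["group"].isin(("YY", "YO")) & (sheet["role"] == "before")
    ).to_numpy()
    if not ref.any():
        ref = np.ones(n, dtype=bool)
    pred = clock.intercept + sigma_t * u
    k_const = 0.0
    c_active = clock.coefficients[clock.coefficients != 0]
    for j in range(len(c_active)):
        k_const += c_active[j] * np.median(rows[j][ref])
    true_signal = pred - k_const
    truth = SimTruth(
        seed=seed,
        sample_targets=pd.DataFrame(
            {
                "sample_id": samples,
                "group": sheet["group"].to_numpy(),
                "role": sheet["role"].to_numpy(),
                "target_raw": t,
                "true_signal": true_signal,
            }
        ),
        group_shifts={g: (group_shifts or {}).get(g, 0.0) for g in TRANSPLANT_GROUPS},
        gene_lfc=lfc,
        donor_changes=donor_change,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    sheet: pd.DataFrame,
    clock: ClockModel,
    age_slope: float = 0.0,
    group_shifts: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    n_cpgs: int = 200,
    bad_detection_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, pd.DataFrame, SimTruth]:
    """Simulate a methylation beta matrix carrying an exact clock signal.

    The clock is applied directly to beta values, so the signal is written
    into the clock CpGs analytically: beta_i = b_i + c_i q_s / sum(c^2) with
    q_s = t_s - intercept - sum(c_i b_i), giving prediction == t_s exactly at
    noise_sd = 0 (up to [0,1] clipping). ``bad_detection_fraction`` of the
    non-clock entries receive detection p > 0.01 to exercise the CpG filter.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples = sheet["sample_id"].tolist()
    n = len(samples)
    t = _target_trajectory(sheet, age_slope, group_shifts or {})

    clock_feats = list(clock.features)
    other = [f"cgX{i:05d}" for i in range(max(0, n_cpgs - len(clock_feats)))]
    cpgs = clock_feats + other

    c = clock.coefficients
    c2 = float(c @ c)
    if c2 == 0:
        beta_clock = np.tile(rng.uniform(0.35, 0.65, size=len(clock_feats))[:, None], (1, n))
    else:
        # max-norm-optimal allocation: every CpG moves by |q| / sum|c|, the
        # smallest possible worst-case excursion, keeping beta inside [0, 1]
        # for moderate signal amplitudes. The baseline is recentered along
        # sign(c) so only the mean-centered target remains in the excursion.
        s1 = float(np.abs(c).sum())
        direction = np.sign(c) / s1
        b = rng.uniform(0.48, 0.52, size=len(clock_feats))
        b = b + direction * (t.mean() - clock.intercept - float(c @ b))
        q = t - clock.intercept - float(c @ b)
        beta_clock = b[:, None] + np.outer(direction, q)
    beta_other = rng.uniform(0.05, 0.95, size=(len(other), n))
    beta = np.vstack([beta_clock, beta_other]) if other else beta_clock
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, size=beta.shape)
    clipped = np.clip(beta, 0.0, 1.0)

    detection_p = np.full(beta.shape, 1e-3)
    if bad_detection_fraction > 0 and other:
        mask = rng.random((len(other), n)) < bad_detection_fraction
        detection_p[len(clock_feats):][mask] = 0.5

    matrix = OmicsMatrix(pd.DataFrame(clipped, index=cpgs, columns=samples), "beta")
    pmat = pd.DataFrame(detection_p, index=cpgs, columns=samples)
    truth = SimTruth(
        seed=seed,
        sample_targets=pd.DataFrame(
            {
                "sample_id": samples,
                "group": sheet["group"].to_numpy(),
                "role": sheet["role"].to_numpy(),
                "target_raw": t,
                "true_signal": t,
            }
        ),
        group_shifts={g: (group_shifts or {}).get(g, 0.0) for g in TRANSPLANT_GROUPS},
    )
    return matrix, pmat, truth


# ---------------------------------------------------------------------------
# Screen-style paired expression data
# ---------------------------------------------------------------------------

def simulate_screen_data(
    n_genes: int = 1000,
    n_planted: int = 50,
    slope: float = 1.0,
    noise_sd: float = 0.5,
    n_donors: int = 12,
    dtage_sd: float = 2.0,
    seed: int = 0,
) -> dict:
    """Paired Before/After expression values whose After-Before change in a
    planted subset of genes scales linearly with a per-donor age-change
    covariate (slope per clock unit); the rest are null. Returns the value
    matrix, sample sheet, per-donor delta, and the planted gene set."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted = genes[:n_planted]
    donors = [f"d{i}" for i in range(n_donors)]
    delta = pd.Series(rng.normal(0.0, dtage_sd, size=n_donors), index=donors, name="dtage")
    records, cols = [], []
    for d in donors:
        for role in ("before", "after"):
            sid = f"{d}_{role}"
            records.append((sid, d, "OY", role, 0.0))
            cols.append(sid)
    sheet = pd.DataFrame(records, columns=["sample_id", "donor_id", "group", "role", "age_months"])
    sheet["batch"] = "b1"
    base = rng.normal(8.0, 1.0, size=n_genes)
    values = np.tile(base[:, None], (1, len(cols)))
    after = (sheet["role"] == "after").to_numpy()
    donor_delta = sheet["donor_id"].map(delta).to_numpy()
    slopes = np.zeros(n_genes)
    slopes[:n_planted] = slope
    values = values + np.outer(slopes, after * donor_delta)
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return {
        "values": pd.DataFrame(values, index=genes, columns=cols),
        "sheet": sheet,
        "dtage": delta,
        "planted": planted,
    }


# ---------------------------------------------------------------------------
# Histology rendering
# ---------------------------------------------------------------------------

def render_adipose_image(
    n_droplets: int = 6,
    radius_lognormal: tuple[float, float] = (4.15, 0.08),
    n_nuclei: int = 20,
    collagen_fraction_target: float = 0.0,
    size: tuple[int, int] = (512, 512),
    nucleus_radius: tuple[int, int] = (8, 14),
    margin: int = 25,
    droplets: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an H&E-like adipose section with known object truth.

    Lipid droplets are non-overlapping near-white disks (radius drawn
    lognormal in px), nuclei small purple disks, collagen pixels drawn inside
    the trichrome classification range at an exact pixel count hitting the
    requested fraction of non-white tissue area. ``droplets`` may supply
    explicit (row, col, radius) placements, bypassing rejection sampling.
    Returns the uint8 RGB image and the truth object table.
    """
    rng = np.random.default_rng(seed)
    h, wd = size
    img = np.empty((h, wd, 3), dtype=np.uint8)
    img[...] = TISSUE_RGB
    yy, xx = np.mgrid[0:h, 0:wd]

    placed: list[tuple[int, int, int]] = []
    if droplets is not None:
        placed = [tuple(map(int, d)) for d in droplets]
        for r0, c0, rad in placed:
            if rad <= 0 or not (0 <= r0 < h and 0 <= c0 < wd):
                raise ValueError("explicit droplet centers must lie inside the image with radius > 0")
    else:
        attempts = 0
        mu, sg = radius_lognormal
        while len(placed) < n_droplets:
            if attempts >= MAX_PLACEMENT_ATTEMPTS:
                raise RuntimeError(
                    f"could not place {n_droplets} non-overlapping droplets after "
                    f"{MAX_PLACEMENT_ATTEMPTS} attempts (placed {len(placed)})"
                )
            attempts += 1
            rad = int(round(float(rng.lognormal(mu, sg))))
            if rad < 2:
                continue
            r0 = int(rng.integers(margin + rad, h - margin - rad)) if h - 2 * (margin + rad) > 0 else None
            c0 = int(rng.integers(margin + rad, wd - margin - rad)) if wd - 2 * (margin + rad) > 0 else None
            if r0 is None or c0 is None:
                raise ValueError("image too small for the requested droplet radii")
            if all((r0 - r1) ** 2 + (c0 - c1) ** 2 > (rad + rr + 3) ** 2 for r1, c1, rr in placed):
                placed.append((r0, c0, rad))

    droplet_mask = np.zeros((h, wd), dtype=bool)
    rows = []
    for i, (r0, c0, rad) in enumerate(placed):
        disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
        droplet_mask |= disk
        img[disk] = DROPLET_RGB
        rows.append((i, "droplet", r0, c0, rad))

    nucleus_mask = np.zeros((h, wd), dtype=bool)
    attempts = 0
    n_placed_nuc = 0
    while n_placed_nuc < n_nuclei and attempts < MAX_PLACEMENT_ATTEMPTS:
        attempts += 1
        rad = int(rng.integers(nucleus_radius[0], nucleus_radius[1] + 1))
        r0 = int(rng.integers(rad, h - rad))
        c0 = int(rng.integers(rad, wd - rad))
        disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
        if (droplet_mask[disk]).any() or (nucleus_mask[disk]).any():
            continue
        nucleus_mask |= disk
        img[disk] = NUCLEUS_RGB
        rows.append((len(rows), "nucleus", r0, c0, rad))
        n_placed_nuc += 1

    if collagen_fraction_target > 0:
        tissue_area = h * wd - int(droplet_mask.sum())  # white space = droplet interiors
        k = int(round(collagen_fraction_target * tissue_area))
        free = ~droplet_mask & ~nucleus_mask
        free_idx = np.flatnonzero(free.ravel())
        if k > len(free_idx):
            raise ValueError("not enough free tissue pixels to reach the collagen target")
        chosen = rng.choice(free_idx, size=k, replace=False)
        flat = img.reshape(-1, 3)
        flat[chosen] = COLLAGEN_RGB

    truth = pd.DataFrame(rows, columns=["object_id", "class", "center_row", "center_col", "radius"])
    return img, truth


# ---------------------------------------------------------------------------
# Mitochondria volume rendering
# ---------------------------------------------------------------------------

def render_mito_volume(
    n_objects: int = 10,
    ball_fraction: float = 0.5,
    radius_um: tuple[float, float] = (0.4, 0.8),
    rod_length_um: tuple[float, float] = (2.0, 4.0),
    shape: tuple[int, int, int] = (41, 96, 96),
    voxel_dims: tuple[float, float, float] = (0.3, 0.1625, 0.1625),
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a labeled 3D volume of balls and rods (capsules) in um space.

    Objects are placed without touching (rejection sampling on padded
    bounding spheres); the truth table carries the analytic volume and class
    of every object. Labels are uint16, 0 = background.
    """
    if n_objects > 65535:
        raise OverflowError("label count exceeds uint16 range")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dz, dy, dx = voxel_dims
    vol = np.zeros(shape, dtype=np.uint16)
    zz = np.arange(nz)[:, None, None] * dz
    yy = np.arange(ny)[None, :, None] * dy
    xx = np.arange(nx)[None, None, :] * dx
    extent = (nz * dz, ny * dy, nx * dx)

    placed: list[tuple[np.ndarray, float]] = []  # (center_um, bounding radius)
    rows = []
    attempts = 0
    label = 0
    while label < n_objects:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {n_objects} non-touching objects after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts (placed {label})"
            )
        attempts += 1
        is_ball = rng.random() < ball_fraction
        r = float(rng.uniform(*radius_um))
        length = 0.0 if is_ball else float(rng.uniform(*rod_length_um))
        bound = r + length / 2
        center = np.array([rng.uniform(bound + dz, e - bound - dz) for e in extent])
        if any(np.linalg.norm(center - c0) < bound + b0 + 2 * max(voxel_dims) for c0, b0 in placed):
            continue
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        d = np.stack(
            np.broadcast_arrays(zz - center[0], yy - center[1], xx - center[2]), axis=-1
        )
        if is_ball:
            mask = (d**2).sum(axis=-1) <= r**2
            true_vol = 4.0 / 3.0 * np.pi * r**3
            cls = "ball"
        else:
            # capsule: distance to the central segment of half-length L/2
            proj = np.clip(d @ axis, -length / 2, length / 2)
            closest = d - proj[..., None] * axis
            mask = (closest**2).sum(axis=-1) <= r**2
            true_vol = np.pi * r**2 * length + 4.0 / 3.0 * np.pi * r**3
            cls = "rod"
        if vol[mask].any() or not mask.any():
            continue
        label += 1
        vol[mask] = label
        placed.append((center, bound))
        rows.append((label, cls, *center, r, length, true_vol))

    truth = pd.DataFrame(
        rows,
        columns=["label", "class", "z_um", "y_um", "x_um", "radius_um", "length_um", "volume_um3"],
    )
    return vol, truth
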