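# Methods

`adipoclock` re-implements, as a tested pipeline, the statistical machinery of
a longitudinal heterochronic adipose-transplantation study: linear
aging/mortality clocks applied to bulk expression and methylation data,
within-donor and between-group age-dynamics statistics, decomposition of
clock predictions into per-gene contributions, a screen for genes tracking
age dynamics, and morphometry of adipose histology. This note records the
models, the assumptions behind them, the parameters that matter, and the
design choices made where the procedure was genuinely open.

## Study design and containers

The design has four transplant groups named donor-to-host — YY
(young-to-young), YO (young-to-old), OY (old-to-young), OO (old-to-old) —
plus sham-operated controls. Each transplant donor yields three samples:
graft tissue **before** transplantation, the same graft **after** ~10 weeks
in the host, and the host's untouched **native** depot; sham animals are
sampled at both time points. Sample sheets carry
`sample_id, donor_id, group, role, age_months, batch`. Default ages are 4
months (young) and 18 months (old) with a 2.3-month follow-up; the sham
group mixes young and old animals so the age calibration (below) has age
spread. Omics matrices are features × samples DataFrames tagged `counts`
(non-negative) or `beta` (methylation fraction in [0, 1]).

## Linear clocks

A clock is a sparse linear predictor over named features:
`value = intercept + Σᵢ cᵢ xᵢ`, with a target scale of either chronological
age or log-hazard (mortality clocks). Published clocks of this family are
penalized linear fits (elastic net / Bayesian ridge), so a coefficient
vector plus intercept, per-feature imputation means, and an optional
prediction sd fully describe them; the package defines a JSON/TSV file
format and ships a generator for synthetic clocks. Kernel (SVM) mortality
clocks are out of scope; a linear representation on β values stands in.

### Expression preprocessing

Five steps, in a fixed order recorded in the provenance of every processed
matrix:

1. **RLE normalization** — per-sample size factor = median ratio to the
   per-gene geometric-mean reference, computed over genes positive in all
   samples. Note the reference itself depends on all samples: scaling one
   sample by *f* rescales every normalized value by the common factor
   f^(1/n). Relative expression is exactly preserved; absolute values are
   defined only up to that scalar.
2. **log2(x + 1)** — the log base is not dictated by the procedure being
   reproduced; base 2 is the field convention for expression.
3. **Per-feature z-scaling** across samples (ddof 0); zero-variance
   features are left at 0 rather than NaN.
4. **Imputation** — clock features absent from the data enter as constant
   rows at their stored means. Placing this after scaling means the stored
   means live on the processed scale, matching their "precomputed average"
   role; a constant row contributes a constant to every prediction.
5. **Centering** to the per-feature median of the reference samples —
   young donor tissue before transplantation (the `before` samples of YY
   and YO) by default. After this step the reference-group median of every
   feature is 0 by construction.

Expression enters the pipeline only after the non-expression filter
(≥ 10 reads in ≥ 20 % of samples, both inclusive). Methylation clocks skip
this pipeline: they apply directly to β values after the CpG detection
filter (drop CpGs with detection p > 0.01 in ≥ 25 % of samples), with
missing clock CpGs imputed from the stored means.

Methylation summaries: per-sample mean β, and Shannon entropy as the mean
per-CpG binary entropy, base-2 logs, with β clamped to [1e-6, 1−1e-6]
— the procedure names entropy without a formula; this is the standard
methylation-entropy definition and is maximal (exactly 1 bit) at β ≡ 0.5.

Module-specific clock outputs are z-scored within each experimental group
(n−1 denominator) before Before/After comparison; constant or singleton
groups are errors, not silent NaNs.

## Longitudinal statistics

* **Within-group contrasts** — `y ~ role + donor`, OLS with treatment
  coding (reference role `before`). The categorical donor term makes the
  role contrast a paired, within-animal comparison; the estimator is
  invariant to any per-donor additive offset. "ANOVA" here means
  coefficient t-tests from this linear model; no sum-of-squares type is
  imposed.
* **Between-group dynamics** — `y ~ stage * group` over the Before/After
  samples of a pair of groups; the interaction coefficient is the second
  group's Before→After change minus the first's.
* **Measurement-error mixed model** — clock predictions that carry a
  per-sample sd are compared with
  `y = Xβ + b_donor + ε`, `b ~ N(0, σ²_d)`, `εᵢ ~ N(0, σ²_r + sᵢ²)`,
  where `sᵢ` is the stated prediction sd (a *known* per-observation
  measurement variance) and X holds intercept, role and batch dummies. The
  two free components (σ²_d, σ²_r) are estimated by REML — the likelihood
  with known heteroscedastic offsets is not available in the installed
  mixed-model routines, so the profiled REML criterion is optimized
  directly (Nelder–Mead over log-variances, Woodbury identity per donor
  block, multiple starts). With equal sᵢ and a balanced paired design the
  fixed-effect estimate coincides with the paired OLS contrast, which the
  tests verify; rescaling all sᵢ leaves the point estimate unchanged.
  Only a single random intercept (donor) is supported; random slopes are
  out of scope.
* **Sham calibration** — OLS of predicted age on chronological age over
  sham samples only; the age deviation of any sample is
  `prediction − (intercept + slope·age)`. Fewer than two distinct sham ages
  triggers an intercept-only fallback, flagged on the result.
* **BH adjustment** — hand-rolled step-up with monotonicity enforcement.
  The family is always an explicit argument (a vector or a list of
  contrasts), never inferred; the pipeline adjusts within each
  (clock × comparison-set) family.

## Differential change and clock deconvolution

Paired DE fits, per gene, `log2-CPM ~ stage + donor` (vectorized over
genes). CPM uses RLE-normalized counts with a +0.5 pseudocount and **one
common** per-million divisor (the median normalized library size): the RLE
factors already carry the per-sample scaling, and dividing again by
per-sample totals would renormalize twice and shrink genuine fold changes.
The negative-binomial DE framework the original analysis ran (an external
package) is explicitly out of scope; this paired linear model targets the
same scientific object — the paired stage effect — and the simplification
is recorded in the output provenance.

Deconvolution: for clock feature *i*,
`Δᵢ = mean(After) − mean(Before)` on the processed scale and
`contributionᵢ = cᵢ · Δᵢ`. Because the clock is linear, Σ contributions
equals `predict(mean After profile) − predict(mean Before profile)`
*exactly*; the acceptance suite checks the identity to 1e-9 over random
instances. A flag substitutes the DE-model logFC for Δ (closer to how
published contribution plots are often made) at the cost of exactness; the
conservation-exact variant is the default.

The ranking metric for signature analyses is `−log(p)·sgn(logFC)`, natural
log by default (the source does not state the base; it is configurable).
p = 0 is clamped to the smallest positive double with a warning.

The age-dynamics screen regresses each gene's expression on the per-donor
predicted-age change (attributed to After samples; Before samples carry 0)
with stage and donor covariates, BH-adjusts across genes, and reports the
q < 0.05 set ordered by (q, |estimate|, gene) for deterministic output.
Pathway over-representation is the one-sided hypergeometric tail (the
sidedness is a package decision; over-representation is the standard
reading), applied separately to positively and negatively associated
genes. Pearson correlation compares gene-level change vectors across
groups after an inner join on gene IDs (≥ 3 shared genes required).

## Histology

Classification rules (8-bit RGB, all thresholds as the quantification
protocol prints them):

* **Droplet**: mean R, G, B all ≥ 190, area **strictly** > 10,000 px²,
  and no pixel within 20 px of any image edge (the border rule is applied
  to object pixels, not bounding boxes — a stated interpretation).
  Overlapping qualifying masks are resolved greedily by descending area
  (ties by object ID): a mask overlapping an already-retained one is
  dropped.
* **Nucleus**: mean R ≤ 150, G ≤ 150, B ≤ 200, area strictly < 5,000 px².
* **Collagen**: per-pixel R ∈ [170, 220], G ∈ [190, 240], B ∈ [210, 255]
  (inclusive), reported as a fraction of tissue area excluding white space.
  The white-space rule is unstated upstream; the package default is
  min(R, G, B) ≥ 235, which captures droplet lumina, and it is
  configurable and recorded in output provenance.

Droplet size statistics use natural-log areas (the log base is a package
decision, flagged in provenance): mean, sd (n−1), `sem = sd/√n`, and the
normal-theory `sem(sd) = √(sd²/(2(n−1)))`, over a seeded subsample of at
most 200 droplets per sample (mirroring 50–200 adipocytes per animal).

The default segmentation backend is classical — brightness threshold
(all channels ≥ 190), hole filling, 8-connected components, watershed on
distance-transform maxima — standing in for the external neural segmenter,
whose printed settings (minimum mask area 0 px, predicted-IoU 0.5,
stability 0.8) are recorded in the configuration for provenance only;
externally produced label masks are accepted as input. A companion
connected-components segmenter over the purple range feeds the nucleus
classifier.

3D morphometry: per-object volume = voxel count × voxel volume; surface
area from a marching-cubes iso-surface at the stated voxel spacing, after a
mild Gaussian smoothing (σ = 0.6 voxel) of the binary mask — raw binary
marching cubes overestimates a ball's surface by ~9 % (staircase), and with
this smoothing a radius-10-voxel ball scores ψ ≈ 0.985. Sphericity
ψ = π^(1/3)(6V)^(2/3)/A, clamped at 1.05 to absorb residual discretization
overshoot in very small objects. Density = object count / cytoplasmic
volume, where the cytoplasm is a caller-supplied mask or explicit volume
(defaulting to the full field); no automatic nucleus-distance exclusion is
invented. Anisotropic voxels are handled geometrically but still recorded
as a warning unless explicitly allowed. Stack depth is n_slices × step
(41 × 0.3 µm = 12.3 µm, the instrument pairing).

## Synthetic data: what it emulates and what it does not

The generators plant known effects so every stage is testable without the
(unreleased) animal data.

**Expression.** The clock signal is planted in the *processed* feature
space and inverted to counts. Per-feature z-scaling pins every processed
row to mean 0 / sd 1 across samples, which has two consequences the
generator works around analytically: (i) only the standardized shape of a
target trajectory is representable, with amplitude at most Σ|cᵢ| (the
generator errors beyond that capacity); (ii) the population mean of
predictions is fixed up to the centering constant, so the recorded truth
includes a common additive offset. The construction splits the active clock
features into two sum-balanced sets and writes
`sign(cᵢ)(cos θ_g · u + sin θ_g · w)` into each row (u = standardized
target, w an orthonormal nuisance direction), with the two angles solving a
triangle so that the coefficient-weighted sum is exactly `sd(t)·u`.
Before→After differences and the planted group shifts δ_g therefore survive
preprocessing exactly. Counts are negative binomial with
Var = µ + φµ² (gamma–Poisson); φ = 0 yields deterministic rounded means
with library factors fixed at 1, so the round trip is exact up to count
rounding (|error| < 0.1 clock units at default depths; the β path below is
exact to 1e-12). Optional planted structure: per-gene log2 fold changes in
After samples, donor-level heterogeneity of the clock shift
(N(0, donor_shift_sd²)), and "coupled" genes whose After change is
proportional to the donor's total planted clock change — the targets of
the screen. Default study conditions: 8 donors per group, 6 shams,
dispersion 0.1, clock of 40 features (80 % density, coefficient scale 0.5),
gene log2-amplitudes 1.0–1.5 (a realistic variable-gene range).

**Methylation.** The clock applies directly to β, so planting is exact:
each clock CpG moves by `sign(cᵢ)·(t_s − t̄)/Σ|c|` around a recentered
baseline near 0.5 — the max-norm-optimal allocation, keeping β inside
[0, 1] for moderate amplitudes (excursions beyond that clip, as flagged).
Detection p-values exercise the CpG filter via a configurable fraction of
bad entries on non-clock CpGs.

**Histology.** Rendered sections place non-overlapping near-white droplet
disks (lognormal radii), purple nucleus disks, and exactly-counted collagen
pixels inside the trichrome range on a pink tissue background; each class
satisfies exactly one classification rule, so truth is recoverable from
color alone. Placement is rejection sampling with a hard cap of 10,000
attempts; a shortfall is an error reporting the achieved count. 3D volumes
contain non-touching balls and capsules with analytic truth volumes.

The generators do **not** emulate: immune-infiltration cell mixtures or
compositional shifts, real H&E texture and stain variability, array probe
chemistry, batch effects beyond a label, or spatial correlation in
histology. Passing tests therefore demonstrate that the *procedures* are
correct and well calibrated under their stated models — not that the
biological conclusions transfer to real tissue.

## Numerical choices and degenerate inputs

Single seeds drive all randomness (one `numpy` Generator per call; no
global state); identical seeds give byte-identical outputs, verified on the
full pipeline. Degenerate designs fail loudly: confounded role/donor
factors raise rank errors, constant groups refuse to standardize, empty
matrices and empty universes are errors. Significant-set orderings break
ties deterministically. BH is compared against the independent
`statsmodels` implementation in tests; the mixed model is checked against
its OLS reduction; geometry measures are checked against analytic volumes
and a per-pixel brute-force classifier.

## Problem sizes

The validation suite runs at desk scale chosen to keep the full test run
around half a minute: 100 simulated studies for planted-shift recovery
(8 donors/group, 300 genes), 1,000 null simulations for type-I control,
50 seeds × 1,000 genes for the screen, 50 rendered 384² sections for the
histology oracle, and 41 × 96² voxel stacks for morphometry. The headline
biological numbers of the study this mirrors (tAge shifts, gene counts,
correlation values) depend on unreleased animal data and are not
reproduced; validation is property-based throughout.

## Known limitations

* Linear clocks only; kernel mortality clocks must be linearized upstream.
* The paired log-CPM DE model does not model count overdispersion
  gene-by-gene; p-values under extreme dispersion heterogeneity are
  approximate (the planted-recovery and FDR simulations bound the practical
  impact at the study's conditions).
* One random intercept; no random slopes or crossed random effects.
* The classical droplet segmenter assumes bright droplets on darker tissue
  and can merge droplets whose boundary brightness exceeds the threshold;
  external masks bypass it.
* β clipping silently truncates planted methylation signals whose
  amplitude exceeds the clock's capacity around the baseline.
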