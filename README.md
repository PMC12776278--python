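# adipoclock

Longitudinal tissue-age analysis for heterochronic adipose-tissue
transplantation.

When white adipose tissue (WAT) is grafted between young and old animals —
young-to-young (YY), young-to-old (YO), old-to-young (OY), old-to-old (OO),
plus sham-operated controls — the biological age of each graft can be
tracked by sampling the same tissue before and after its stay in the host.
`adipoclock` implements the full quantitative pipeline for such a study,
for researchers analyzing transplant or intervention designs with aging
clocks:

* **Clocks** (`clockcore`): linear aging/mortality clocks
  (`value = intercept + Σᵢ cᵢ xᵢ`) applied to bulk RNA-seq after the
  standard preprocessing chain — RLE (median-of-ratios) normalization,
  log2(x+1), per-feature z-scaling, imputation of missing clock genes,
  centering to the young-donor baseline profile — and to methylation β
  values after CpG detection-p filtering; plus per-sample mean methylation
  and Shannon entropy.
* **Longitudinal statistics** (`longstats`): paired Before/After/Native
  contrasts with the donor as covariate; stage × group interactions for
  between-group dynamics; a REML mixed model with a donor random intercept
  and known per-prediction measurement variance; sham-based calibration of
  expected age (`tAge ~ age` on shams) and per-sample age deviations;
  Benjamini–Hochberg adjustment over explicit families.
* **Deconvolution** (`deconv`): paired differential expression on log2-CPM;
  decomposition of a clock's predicted age change into per-gene
  contributions `Δ(processed expression) × coefficient`, which sum
  *exactly* to the predicted mean-profile difference; the signed
  `−log(p)·sgn(logFC)` ranking metric; a screen for genes whose expression
  change tracks per-donor age dynamics; Fisher-exact pathway
  over-representation; cross-group Pearson comparison of change vectors.
* **Histology** (`histoquant`): lipid-droplet classification (mean RGB
  ≥ 190 on all channels, area > 10,000 px², 20-px border exclusion,
  largest-mask overlap resolution), nucleus classification (R ≤ 150,
  G ≤ 150, B ≤ 200, area < 5,000 px²), collagen fraction from trichrome
  color ranges, log-scale droplet size/heterogeneity statistics, and 3D
  mitochondrial morphometry (volume, marching-cubes surface, sphericity
  ψ = π^{1/3}(6V)^{2/3}/A, density).
* **Synthetic data** (`synthdata`): the full transplant design with planted
  ground truth — clock signals that survive preprocessing exactly,
  negative-binomial counts, methylation with detection p-values, rendered
  H&E-like sections and labeled 3D stacks — so every stage is testable
  without animal data.

`pipeline_io` ties the stages together behind a YAML config, a report
directory of TSVs with a provenance manifest, and an `adipoclock` CLI
(`simulate`, `clock-predict`, `histo`, `report`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1; outputs under `results/`):

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_clock_ages.py
python analysis/03_longitudinal_contrasts.py
python analysis/04_clock_deconvolution.py
python analysis/05_histology.py --seed 1
```

Step 01 simulates 108 samples (8 donors per transplant group + 6 shams)
with planted mean Before→After clock shifts of +2 (YY), +4 (YO),
**−5 (OY)** and +2 (OO) clock units plus donor-level heterogeneity
(sd 1.5) — the OY group is the planted rejuvenation. Steps 02–05 then
print:

```
tAge Before->After estimates: YY +0.86 , YO +3.69*, OY -4.44*, OO +2.81*
eAge Before->After estimates: YY +1.95*, YO +4.04*, OY -5.00*, OO +1.97*
group pairs with significantly different age dynamics (q<0.05): ['YY_vs_YO', 'YY_vs_OY', 'YO_vs_OY', 'OY_vs_OO']
OY: 33 DE genes (q<0.05); predicted age change from deconvolution -4.44
age-dynamics screen: 21 genes at q<0.05
droplets: 5 kept (truth 5), 20 nuclei; mean log area 9.426 (sd 0.143); collagen fraction 0.100 (target 0.100)
stack depth 12.3 um; 8 mitochondria, density 0.002673/um^3; mean sphericity ball 1.047, rod 0.811
```

Reading the output: the paired contrasts recover every planted shift with
the right sign (`*` = BH-adjusted p < 0.05; tAge estimates wobble around
the planted means because of count noise and donor heterogeneity, while
the noiseless methylation clock recovers −5.00 exactly); the only
rejuvenating group is OY, and its dynamics differ significantly from both
isochronic controls. The deconvolution total equals the estimated tAge
change by construction (the conservation identity), the screen's hits are
the genes planted to track per-donor age dynamics (the 20-gene coupled
block is recovered at q ≈ 0 in the enrichment step), and the histology
readouts match the rendered truth — droplet count, collagen fraction to
three decimals, and rods scoring lower sphericity than balls.

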