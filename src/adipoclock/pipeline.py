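"""End-to-end orchestration of the transplant-age analysis.

``run_pipeline`` chains the stages on simulated or user-supplied inputs:
simulate (optional) -> expression/methylation filters -> clock preprocessing
-> age predictions -> sham calibration and age deviations -> within-group
paired contrasts and between-group interaction contrasts -> paired DE, clock
deconvolution, age-dynamics screen and enrichment -> histology
quantification. Every emitted table is collected in a :class:`RunReport`
whose manifest records the stage, parameters, and seed that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import clockcore, deconv, histoquant, longstats, synthdata
from .config import RunConfig
from .types import SHAM_GROUP, TRANSPLANT_GROUPS, OmicsMatrix


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, table: pd.DataFrame, stage: str, **params) -> None:
        self.tables[name] = table
        self.provenance[name] = {"stage": stage, "params": params}

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"warnings": self.warnings, "tables": {}}
        for name, table in self.tables.items():
            path = outdir / f"{name}.tsv"
            table.to_csv(path, sep="\t", float_format="%.10g")
            manifest["tables"][name] = {"path": path.name, **self.provenance[name]}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return outdir


def _contrast_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": key,
                "term": r.term,
                "estimate": r.estimate,
                "se": r.se,
                "p": r.p,
                "p_adj": r.p_adj,
                "n": r.n,
                "model": r.model,
            }
            for key, r in results
        ]
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``; deterministic for a
    fixed seed. Any stage failure aborts with a stage-tagged error."""
    report = RunReport()
    rng_seed = int(config.seed)
    thresholds = config.thresholds
    q_thresh = thresholds["significance_q"]

    # ------------------------------------------------------------- inputs
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = config.simulate
            spec = synthdata.DesignSpec(
                donors_per_group=sim.donors_per_group,
                n_sham=sim.n_sham,
                young_age=sim.young_age,
                old_age=sim.old_age,
                followup_months=sim.followup_months,
                n_batches=sim.n_batches,
                seed=rng_seed,
            )
            sheet = synthdata.generate_design(spec)
            clock = synthdata.generate_linear_clock(
                n_features=sim.clock_features,
                density=sim.clock_density,
                coef_scale=sim.clock_coef_scale,
                intercept=sim.clock_intercept,
                seed=rng_seed + 1,
            )
            de_genes = {
                f"G{i:05d}": sim.de_lfc
                for i in range(sim.clock_features, sim.clock_features + sim.n_de_genes)
            }
            counts, truth = synthdata.simulate_expression(
                sheet,
                clock,
                age_slope=sim.age_slope,
                group_shifts=sim.group_shifts,
                dispersion=sim.dispersion,
                n_genes=sim.n_genes,
                gene_lfc=de_genes,
                seed=rng_seed + 2,
            )
            meth_clock = synthdata.generate_linear_clock(
                n_features=min(40, sim.n_cpgs),
                density=1.0,
                coef_scale=0.5,
                intercept=sim.clock_intercept,
                feature_prefix="cg",
                seed=rng_seed + 3,
            )
            beta, detp, meth_truth = synthdata.simulate_methylation(
                sheet,
                meth_clock,
                group_shifts=sim.group_shifts,
                noise_sd=sim.methylation_noise_sd,
                n_cpgs=sim.n_cpgs,
                bad_detection_fraction=0.02,
                seed=rng_seed + 4,
            )
            report.add("sample_sheet", sheet, stage, seed=rng_seed)
            report.add("sim_truth_samples", truth.sample_targets, stage, seed=rng_seed)
        else:
            from . import io as _io

            if not (config.sample_sheet and config.counts and config.clock):
                raise ValueError("need sample_sheet, counts and clock paths (or a simulate block)")
            sheet = _io.read_sample_sheet(config.sample_sheet)
            counts = _io.read_matrix(config.counts, "counts")
            clock = _io.read_clock(config.clock)
            truth = None
            beta = detp = meth_clock = None
            if config.beta and config.detection_p:
                beta = _io.read_matrix(config.beta, "beta")
                sep = "\t" if str(config.detection_p).endswith(".tsv") else ","
                detp = pd.read_csv(config.detection_p, sep=sep, index_col=0)
                if config.methylation_clock:
                    meth_clock = _io.read_clock(config.methylation_clock)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ------------------------------------------------------ expression QC
    stage = "expression_filter"
    try:
        filtered = clockcore.filter_expression(
            counts,
            min_reads=int(thresholds["expression_min_reads"]),
            min_fraction=thresholds["expression_min_fraction"],
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # -------------------------------------------------------- methylation
    if beta is not None:
        stage = "methylation"
        try:
            kept = clockcore.filter_methylation(
                beta,
                detp,
                p_thresh=thresholds["methylation_detection_p"],
                frac=thresholds["methylation_bad_fraction"],
            )
            msummary = pd.DataFrame(
                {
                    "mean_methylation": clockcore.mean_methylation(kept),
                    "shannon_entropy": clockcore.shannon_entropy(kept),
                }
            )
            report.add("methylation_summary", msummary, stage)
            if meth_clock is not None:
                bmat = clockcore.impute_features(kept.data, meth_clock)
                epreds = clockcore.predict_age(meth_clock, bmat)
                report.add("eage_predictions", epreds, stage, clock=meth_clock.name)
                eage = pd.Series(
                    epreds["prediction"].to_numpy(), index=epreds["sample_id"], name="eage"
                )
                rows = []
                for g in TRANSPLANT_GROUPS:
                    sub = sheet[sheet["group"] == g]
                    for r in longstats.adjust_family(longstats.paired_contrast(eage, sub)):
                        rows.append((g, r))
                report.add("eage_contrasts", _contrast_frame(rows), stage)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, str(e)) from e

    # ------------------------------------------------ clock preprocessing
    stage = "clock_predict"
    try:
        processed = clockcore.preprocess_for_clock(filtered, clock, sheet)
        preds = clockcore.predict_age(clock, processed)
        report.add("tage_predictions", preds, stage, clock=clock.name, steps=processed.steps)
        tage = pd.Series(preds["prediction"].to_numpy(), index=preds["sample_id"], name="tage")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ------------------------------------------------- sham calibration
    stage = "sham_calibration"
    try:
        sham = sheet[sheet["group"] == SHAM_GROUP]
        if len(sham):
            calib = longstats.sham_calibrate(
                sham["age_months"].to_numpy(), tage.loc[sham["sample_id"]].to_numpy()
            )
            dev = longstats.age_deviation(
                calib, sheet["age_months"].to_numpy(), tage.loc[sheet["sample_id"]].to_numpy()
            )
            deviations = pd.DataFrame(
                {"sample_id": sheet["sample_id"], "age_deviation": dev}
            )
            report.add(
                "age_deviations",
                deviations,
                stage,
                slope=calib.slope,
                intercept=calib.intercept,
                intercept_only=calib.intercept_only,
            )
            response = pd.Series(dev, index=sheet["sample_id"].to_numpy(), name="age_deviation")
        else:
            report.warnings.append("no sham samples; skipping age calibration, using raw predictions")
            response = tage
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ------------------------------------------------- longitudinal stats
    stage = "longitudinal"
    try:
        within_rows = []
        for g in TRANSPLANT_GROUPS:
            sub = sheet[sheet["group"] == g]
            res = longstats.paired_contrast(tage, sub)
            for r in longstats.adjust_family(res):
                within_rows.append((g, r))
        report.add("tage_contrasts", _contrast_frame(within_rows), stage)

        inter = [
            (f"{a}_vs_{b}", longstats.interaction_contrast(response, sheet, (a, b)))
            for a, b in combinations(TRANSPLANT_GROUPS, 2)
        ]
        longstats.adjust_family([r for _, r in inter])
        report.add("dynamics_interactions", _contrast_frame(inter), stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ------------------------------------------------------ deconvolution
    stage = "deconvolution"
    try:
        de_tables = {}
        contribs = []
        change_vectors = {}
        for g in TRANSPLANT_GROUPS:
            de = deconv.paired_de(filtered, sheet, g)
            de_tables[g] = de
            change_vectors[g] = de["logFC"]
            contrib = deconv.gene_contributions(processed, sheet, clock, group=g)
            t = contrib.table.copy()
            t["group"] = g
            t["total"] = contrib.total
            contribs.append(t)
        de_all = pd.concat(de_tables, names=["group", "gene"])
        report.add("paired_de", de_all.reset_index(), stage)
        report.add("gene_contributions", pd.concat(contribs), stage)
        R, P, Q = deconv.correlation_compare(change_vectors)
        report.add("change_correlations", R, stage)

        # per-donor predicted-age change for the screen
        dtage = {}
        for _, row in sheet[sheet["role"] == "after"].iterrows():
            before_id = sheet[
                (sheet["donor_id"] == row["donor_id"]) & (sheet["role"] == "before")
            ]["sample_id"].iloc[0]
            dtage[row["donor_id"]] = tage[row["sample_id"]] - tage[before_id]
        screen = deconv.tage_association_screen(
            deconv.log2_cpm(filtered),
            sheet,
            pd.Series(dtage),
            q_threshold=q_thresh,
        )
        report.add("tage_screen", screen.reset_index(names="gene"), stage)
        if config.pathways:
            from . import io as _io

            pathways = _io.read_gmt(config.pathways)
            universe = set(screen.index)
            up = set(screen.index[screen["significant"] & (screen["estimate"] > 0)])
            down = set(screen.index[screen["significant"] & (screen["estimate"] < 0)])
            enr_up = deconv.fisher_enrichment(up, universe, pathways, q_threshold=q_thresh)
            enr_dn = deconv.fisher_enrichment(down, universe, pathways, q_threshold=q_thresh)
            report.add("enrichment_up", enr_up.reset_index(), stage)
            report.add("enrichment_down", enr_dn.reset_index(), stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---------------------------------------------------------- histology
    if config.simulate is not None and config.simulate.histology:
        stage = "histology"
        try:
            sim = config.simulate
            img, htruth = synthdata.render_adipose_image(
                n_droplets=sim.n_droplets,
                n_nuclei=sim.n_nuclei,
                collagen_fraction_target=sim.collagen_fraction,
                size=(sim.image_size, sim.image_size),
                seed=rng_seed + 5,
            )
            objects = histoquant.segment_droplets_classical(img)
            droplets = histoquant.classify_droplets(objects, img.shape[:2])
            if len(droplets) >= 2:
                summ = histoquant.droplet_summary(
                    droplets["area"].to_numpy(),
                    subsample=int(thresholds["droplet_subsample_max"]),
                    seed=rng_seed,
                )
                droplet_stats = pd.DataFrame([summ.__dict__])
            else:
                droplet_stats = pd.DataFrame()
            frac = histoquant.collagen_fraction(img, white_threshold=int(thresholds["white_threshold"]))
            vol, vtruth = synthdata.render_mito_volume(n_objects=sim.mito_objects, seed=rng_seed + 6)
            morph = histoquant.mito_morphology(vol, (0.3, 0.1625, 0.1625), allow_anisotropy=True)
            report.add("droplet_objects", droplets, stage)
            report.add("droplet_summary", droplet_stats, stage)
            report.add(
                "collagen", pd.DataFrame({"collagen_fraction": [frac]}), stage,
                target=sim.collagen_fraction,
            )
            report.add("mito_morphology", morph.table(), stage, density=morph.density_per_um3)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, str(e)) from e

    return report
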