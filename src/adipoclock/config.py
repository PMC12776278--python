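"""Run configuration: defaults, YAML round-trip, and validation.

Every analysis threshold carries its study default (the values the
classification and filtering rules are defined with); configs are plain
mappings validated against the known key set, so a typo is an error rather
than a silently ignored option.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Analysis thresholds with their default values and the rule each encodes.
#: These are the operative constants of the filtering/classification rules.
DEFAULT_THRESHOLDS: dict[str, tuple[float, str]] = {
    "expression_min_reads": (10, "gene kept with >= 10 reads in >= 20% of samples"),
    "expression_min_fraction": (0.2, "gene kept with >= 10 reads in >= 20% of samples"),
    "methylation_detection_p": (0.01, "CpG dropped when detection p > 0.01 in >= 25% of samples"),
    "methylation_bad_fraction": (0.25, "CpG dropped when detection p > 0.01 in >= 25% of samples"),
    "droplet_rgb_min": (190, "droplet mean RGB >= 190 on all channels"),
    "droplet_area_min": (10_000, "droplet area strictly exceeding 10,000 px^2"),
    "border_margin_px": (20, "masks within 20 px of an image border excluded"),
    "nucleus_r_max": (150, "nucleus mean R <= 150"),
    "nucleus_g_max": (150, "nucleus mean G <= 150"),
    "nucleus_b_max": (200, "nucleus mean B <= 200"),
    "nucleus_area_max": (5_000, "nucleus area strictly below 5,000 px^2"),
    "collagen_r_range": ([170, 220], "collagen R channel in 170-220"),
    "collagen_g_range": ([190, 240], "collagen G channel in 190-240"),
    "collagen_b_range": ([210, 255], "collagen B channel in 210-255"),
    "white_threshold": (235, "white space: min channel >= 235 (package default; rule unstated upstream)"),
    "significance_q": (0.05, "BH-adjusted p < 0.05 declared significant"),
    "droplet_subsample_max": (200, "50-200 adipocytes subsampled per sample"),
    "graft_mass_fraction": (0.01, "graft mass normalized to 1% of recipient body weight"),
    "stack_slices": (41, "stacks cropped to 41 optical slices"),
    "stack_step_um": (0.3, "0.3 um z-step, 41 slices = 12.3 um depth"),
    # external segmentation-backend settings recorded for provenance only
    "sam_min_mask_area": (0, "external segmenter: minimum mask region area 0 px"),
    "sam_pred_iou": (0.5, "external segmenter: predicted IoU threshold 0.5"),
    "sam_stability": (0.8, "external segmenter: stability score threshold 0.8"),
}


@dataclass
class SimulationSpec:
    donors_per_group: int = 8
    n_sham: int = 6
    young_age: float = 4.0
    old_age: float = 18.0
    followup_months: float = 2.3
    n_batches: int = 2
    n_genes: int = 400
    clock_features: int = 40
    clock_density: float = 0.8
    clock_coef_scale: float = 0.5
    clock_intercept: float = 10.0
    age_slope: float = 0.0
    group_shifts: dict = field(default_factory=lambda: {"YY": 2.0, "YO": 4.0, "OY": -5.0, "OO": 2.0})
    dispersion: float = 0.05
    n_cpgs: int = 150
    methylation_noise_sd: float = 0.02
    n_de_genes: int = 20
    de_lfc: float = 1.0
    histology: bool = True
    image_size: int = 640
    n_droplets: int = 5
    n_nuclei: int = 20
    collagen_fraction: float = 0.1
    mito_objects: int = 8


@dataclass
class RunConfig:
    """Full pipeline configuration. ``simulate`` drives the synthetic-data
    path; supplying input paths instead runs on user data."""

    seed: int = 0
    outdir: str = "results/run"
    simulate: SimulationSpec | None = None
    sample_sheet: str | None = None
    counts: str | None = None
    beta: str | None = None
    detection_p: str | None = None
    clock: str | None = None
    methylation_clock: str | None = None
    pathways: str | None = None
    thresholds: dict = field(default_factory=lambda: {k: v for k, (v, _) in DEFAULT_THRESHOLDS.items()})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = payload.get("simulate")
        if sim is not None and not isinstance(sim, SimulationSpec):
            sim_known = set(SimulationSpec.__dataclass_fields__)
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
            payload["simulate"] = SimulationSpec(**sim)
        base_thresholds = {k: v for k, (v, _) in DEFAULT_THRESHOLDS.items()}
        given = payload.get("thresholds") or {}
        unknown_t = set(given) - set(base_thresholds)
        if unknown_t:
            raise ValueError(f"unknown threshold keys: {sorted(unknown_t)}")
        base_thresholds.update(given)
        payload["thresholds"] = base_thresholds
        return cls(**payload)


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(payload)


def save_config(config: RunConfig, path: str | Path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(clean(config.to_dict()), sort_keys=False))
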