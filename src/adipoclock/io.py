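"""Readers and writers for the pipeline's on-disk formats.

Matrices are TSV/CSV with feature IDs in the first column and sample IDs in
the header; clocks are JSON (or a 3-column TSV with '#'-prefixed metadata
header lines); pathway maps are GMT; images are 8-bit RGB PNG and label
volumes 16-bit multi-page TIFF. Writers and readers round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import ClockModel, OmicsMatrix, validate_sample_sheet


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, modality: str) -> OmicsMatrix:
    """Read a features x samples matrix, validating modality constraints.

    Counts must be numeric and >= 0; beta values must lie in [0, 1].
    Duplicate feature IDs and non-numeric cells are errors naming the
    offending rows/cells.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path.name}: {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at feature {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iloc[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value in {path.name} at feature {raw.index[r]!r}, sample {raw.columns[c]!r}")
    values = numeric.to_numpy()
    if modality == "counts" and values.size and values.min() < 0:
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(
            f"negative count in {path.name} at feature {numeric.index[r]!r}, sample {numeric.columns[c]!r}"
        )
    if modality == "beta" and values.size and (values.min() < 0 or values.max() > 1):
        outside = (numeric < 0) | (numeric > 1)
        r, c = np.argwhere(outside.to_numpy())[0]
        raise ValueError(
            f"beta value outside [0,1] in {path.name} at feature {numeric.index[r]!r}, "
            f"sample {numeric.columns[c]!r}: {numeric.iloc[r, c]}"
        )
    return OmicsMatrix(numeric, modality)


def write_matrix(matrix: OmicsMatrix | pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    data = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    data.to_csv(path, sep=_sep_for(path))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(Path(path))
    sheet["batch"] = sheet["batch"].astype(str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Clock files
# ---------------------------------------------------------------------------

def read_clock(path: str | Path) -> ClockModel:
    """Read a clock from JSON, or from a '#'-headed 3-column TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return ClockModel(
            name=payload["name"],
            target=payload["target"],
            features=payload["features"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            imputation_means=np.asarray(payload["imputation_means"], dtype=float),
            sd=float(payload.get("sd", 0.0)),
        )
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("feature\t"):
                feat, coef, mean = line.split("\t")
                rows.append((feat, float(coef), float(mean)))
    if not rows:
        raise ValueError(f"clock file {path.name} contains no features")
    feats, coefs, means = zip(*rows)
    return ClockModel(
        name=meta.get("name", path.stem),
        target=meta.get("target", "chronological_age"),
        features=list(feats),
        coefficients=np.asarray(coefs),
        intercept=float(meta.get("intercept", 0.0)),
        imputation_means=np.asarray(means),
        sd=float(meta.get("sd", 0.0)),
    )


def write_clock(clock: ClockModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "name": clock.name,
            "target": clock.target,
            "intercept": clock.intercept,
            "features": clock.features,
            "coefficients": clock.coefficients.tolist(),
            "imputation_means": clock.imputation_means.tolist(),
            "sd": clock.sd,
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w") as fh:
        fh.write(f"# name = {clock.name}\n# target = {clock.target}\n")
        fh.write(f"# intercept = {clock.intercept!r}\n# sd = {clock.sd!r}\n")
        fh.write("feature\tcoefficient\timputation_mean\n")
        for f, c, m in zip(clock.features, clock.coefficients, clock.imputation_means):
            fh.write(f"{f}\t{float(c)!r}\t{float(m)!r}\n")


# ---------------------------------------------------------------------------
# Pathways, images, volumes
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT pathway map: name <tab> description <tab> member genes."""
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(g for g in parts[2:] if g)
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_image(path: str | Path) -> np.ndarray:
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(path)


def read_label_volume(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_label_volume(volume: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, volume.astype(np.uint16))
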