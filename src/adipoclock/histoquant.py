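"""Adipose histology quantification.

Implements the exact classification rules used for H&E / trichrome
morphometry:

* lipid droplets: segmented regions whose mean RGB is >= 190 on every
  channel, with area strictly exceeding 10,000 px^2, not touching the image
  border within 20 px; overlapping qualifying masks are resolved by keeping
  the largest;
* nuclei: mean R <= 150, G <= 150, B <= 200 and area strictly below
  5,000 px^2;
* collagen: pixels with R in [170, 220], G in [190, 240], B in [210, 255]
  (inclusive), expressed as a fraction of tissue area after excluding white
  space (min channel >= 235, i.e. droplet lumina);
* 3D mitochondria: per-object volume, marching-cubes surface area and the
  isoperimetric sphericity psi = pi^(1/3) (6V)^(2/3) / A.

Droplet size statistics are computed on the natural-log scale over an
optionally subsampled set of 50-200 droplets per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation
from skimage.feature import peak_local_max

DROPLET_RGB_MIN = 190
DROPLET_AREA_MIN = 10_000  # strictly exceeded
BORDER_MARGIN = 20
NUCLEUS_RGB_MAX = (150, 150, 200)
NUCLEUS_AREA_MAX = 5_000  # strictly below
COLLAGEN_RANGES = ((170, 220), (190, 240), (210, 255))
WHITE_THRESHOLD = 235
SPHERICITY_CLAMP = 1.05


@dataclass
class SegmentedObject:
    """A segmented 2D region: pixel coordinates (0-based, row-major) plus
    measurements derived from them and the source image."""

    object_id: int
    rows: np.ndarray
    cols: np.ndarray
    area: int = 0
    mean_rgb: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # min_row, min_col, max_row, max_col
    border: bool = False

    @classmethod
    def from_pixels(cls, object_id: int, rows, cols, image: np.ndarray, margin: int = BORDER_MARGIN) -> "SegmentedObject":
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        h, w = image.shape[:2]
        if rows.size == 0:
            raise ValueError("object has no pixels")
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
            raise ValueError(f"object {object_id} references pixels outside the image")
        colors = image[rows, cols].astype(float)
        border = bool(
            (rows < margin).any()
            or (cols < margin).any()
            or (rows >= h - margin).any()
            or (cols >= w - margin).any()
        )
        return cls(
            object_id=object_id,
            rows=rows,
            cols=cols,
            area=int(rows.size),
            mean_rgb=tuple(colors.mean(axis=0)),
            bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
            border=border,
        )


def objects_from_labels(labels: np.ndarray, image: np.ndarray, margin: int = BORDER_MARGIN) -> list[SegmentedObject]:
    """Build SegmentedObjects from a label image (0 = background)."""
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        out.append(SegmentedObject.from_pixels(int(lab), rows, cols, image, margin))
    return out


_TABLE_COLUMNS = ["object_id", "area", "mean_r", "mean_g", "mean_b", "border"]


def _object_table(objects: list[SegmentedObject]) -> pd.DataFrame:
    if not objects:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.DataFrame(
        [
            {
                "object_id": o.object_id,
                "area": o.area,
                "mean_r": o.mean_rgb[0],
                "mean_g": o.mean_rgb[1],
                "mean_b": o.mean_rgb[2],
                "border": o.border,
            }
            for o in objects
        ]
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_droplets(
    objects: list[SegmentedObject],
    image_shape: tuple[int, int] | None = None,
    area_min: int = DROPLET_AREA_MIN,
    rgb_min: int = DROPLET_RGB_MIN,
) -> pd.DataFrame:
    """Apply the lipid-droplet rules and resolve overlaps.

    Keep iff mean R, G, B all >= ``rgb_min`` AND area > ``area_min`` AND the
    object does not touch the border margin. Among surviving objects whose
    pixel sets overlap, the largest (by area, ties broken by object ID) is
    retained and any object overlapping a retained one is dropped.
    """
    survivors = [
        o
        for o in objects
        if min(o.mean_rgb) >= rgb_min and o.area > area_min and not o.border
    ]
    survivors.sort(key=lambda o: (-o.area, o.object_id))
    if image_shape is None and survivors:
        image_shape = (
            max(o.bbox[2] for o in survivors) + 1,
            max(o.bbox[3] for o in survivors) + 1,
        )
    kept: list[SegmentedObject] = []
    taken = np.zeros(image_shape, dtype=bool) if image_shape else None
    for o in survivors:
        if taken is not None and taken[o.rows, o.cols].any():
            continue
        kept.append(o)
        if taken is not None:
            taken[o.rows, o.cols] = True
    return _object_table(kept)


def classify_nuclei(
    objects: list[SegmentedObject],
    rgb_max: tuple[int, int, int] = NUCLEUS_RGB_MAX,
    area_max: int = NUCLEUS_AREA_MAX,
) -> pd.DataFrame:
    """Nucleus rule: mean R <= 150, G <= 150, B <= 200 and area < 5,000."""
    kept = [
        o
        for o in objects
        if o.mean_rgb[0] <= rgb_max[0]
        and o.mean_rgb[1] <= rgb_max[1]
        and o.mean_rgb[2] <= rgb_max[2]
        and o.area < area_max
    ]
    return _object_table(kept)


# ---------------------------------------------------------------------------
# Droplet statistics
# ---------------------------------------------------------------------------

@dataclass
class DropletSummary:
    n: int
    mean_log_area: float
    sd_log_area: float
    sem_mean: float
    sem_sd: float


def droplet_summary(
    areas,
    subsample: int | None = 200,
    seed: int = 0,
) -> DropletSummary:
    """Log-scale droplet size statistics.

    Natural-log areas; mean and sd (n-1) with their standard errors
    (sem of the sd via the normal-theory approximation sqrt(sd^2/(2(n-1)))).
    When more than ``subsample`` droplets are provided, a seeded random
    subset of that size is used, mirroring per-sample adipocyte subsampling.
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    if subsample is not None and areas.size > subsample:
        rng = np.random.default_rng(seed)
        areas = rng.choice(areas, size=subsample, replace=False)
    if areas.size < 2:
        raise ValueError(f"need >= 2 droplets for summary statistics, got {areas.size}")
    la = np.log(areas)
    n = la.size
    sd = float(la.std(ddof=1))
    return DropletSummary(
        n=n,
        mean_log_area=float(la.mean()),
        sd_log_area=sd,
        sem_mean=sd / np.sqrt(n),
        sem_sd=float(np.sqrt(sd**2 / (2.0 * (n - 1)))),
    )


# ---------------------------------------------------------------------------
# Collagen
# ---------------------------------------------------------------------------

def collagen_fraction(
    image: np.ndarray,
    ranges=COLLAGEN_RANGES,
    white_threshold: int = WHITE_THRESHOLD,
) -> float:
    """Collagen-positive pixel fraction of non-white tissue area.

    A pixel is collagen iff each channel falls inclusively within its
    trichrome range; white space (min channel >= ``white_threshold``, the
    droplet lumina) is excluded from the denominator.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    img = image.astype(np.int64)
    (rlo, rhi), (glo, ghi), (blo, bhi) = ranges
    collagen = (
        (img[..., 0] >= rlo) & (img[..., 0] <= rhi)
        & (img[..., 1] >= glo) & (img[..., 1] <= ghi)
        & (img[..., 2] >= blo) & (img[..., 2] <= bhi)
    )
    white = img.min(axis=2) >= white_threshold
    tissue = int((~white).sum())
    if tissue == 0:
        raise ValueError("tissue area is zero after white-space exclusion")
    return float((collagen & ~white).sum()) / tissue


# ---------------------------------------------------------------------------
# Classical droplet segmentation backend
# ---------------------------------------------------------------------------

def segment_droplets_classical(
    image: np.ndarray,
    rgb_min: int = DROPLET_RGB_MIN,
    min_distance: int = 20,
) -> list[SegmentedObject]:
    """Threshold-and-watershed droplet segmentation.

    Brightness threshold (all channels >= ``rgb_min``) -> hole filling ->
    8-connected components -> watershed split on the maxima of the distance
    transform, so touching droplets separate. An empty result is allowed.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    mask = (image >= rgb_min).all(axis=2)
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    else:
        labels = segmentation.watershed(-dist, markers, mask=mask)
    return objects_from_labels(labels, image)


def segment_nuclei_classical(
    image: np.ndarray,
    rgb_max: tuple[int, int, int] = NUCLEUS_RGB_MAX,
) -> list[SegmentedObject]:
    """Connected components over the purple-staining range (per-pixel
    R <= 150, G <= 150, B <= 200), feeding :func:`classify_nuclei`."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    mask = (
        (image[..., 0] <= rgb_max[0])
        & (image[..., 1] <= rgb_max[1])
        & (image[..., 2] <= rgb_max[2])
    )
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    # offset IDs so they cannot collide with the droplet segmenter's
    return [
        SegmentedObject.from_pixels(int(lab) + 10_000, *np.nonzero(labels == lab), image)
        for lab in range(1, n + 1)
    ]


# ---------------------------------------------------------------------------
# 3D mitochondria morphometry
# ---------------------------------------------------------------------------

@dataclass
class MitoObject:
    label: int
    volume_um3: float
    surface_um2: float
    sphericity: float


@dataclass
class MitoMorphology:
    objects: list[MitoObject]
    density_per_um3: float
    cytoplasm_volume_um3: float
    warnings: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": o.label,
                    "volume_um3": o.volume_um3,
                    "surface_um2": o.surface_um2,
                    "sphericity": o.sphericity,
                }
                for o in self.objects
            ]
        )


def sphericity(volume: float, surface: float, clamp: float = SPHERICITY_CLAMP) -> float:
    """Isoperimetric sphericity pi^(1/3) (6V)^(2/3) / A, clamped to <= 1.05
    to absorb voxel-discretization overshoot."""
    if volume <= 0 or surface <= 0:
        raise ValueError("volume and surface must be positive")
    return min(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface, clamp)


def mito_morphology(
    labels: np.ndarray,
    voxel_dims: tuple[float, float, float],
    cytoplasm_mask: np.ndarray | None = None,
    cytoplasm_volume_um3: float | None = None,
    allow_anisotropy: bool = False,
) -> MitoMorphology:
    """Per-object 3D morphometry and mitochondrial density.

    Volume is voxel count x voxel volume; surface area comes from a
    marching-cubes iso-surface of each object's binary mask at the stated
    voxel spacing (so anisotropy is respected geometrically; a warning is
    still recorded for anisotropic voxels unless ``allow_anisotropy``).
    Density is object count divided by the cytoplasmic volume -- taken from
    ``cytoplasm_mask`` (volume of its True voxels) or
    ``cytoplasm_volume_um3``, defaulting to the full field volume.
    """
    if labels.ndim != 3:
        raise ValueError("expected a 3D label volume")
    dz, dy, dx = (float(v) for v in voxel_dims)
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel dimensions must be positive")
    warns: list[str] = []
    if not allow_anisotropy and len({dz, dy, dx}) > 1:
        warns.append(
            f"anisotropic voxels {voxel_dims}; surface areas use the stated spacing"
        )
    voxel_volume = dz * dy * dx
    objects = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        count = int(mask.sum())
        vol = count * voxel_volume
        # mild Gaussian smoothing before iso-surfacing suppresses the
        # staircase overestimate of marching-cubes surface areas (~+9% for a
        # binary ball); fall back to the raw mask for objects too small to
        # survive smoothing
        padded = np.pad(mask, 2).astype(float)
        smoothed = ndimage.gaussian_filter(padded, 0.6)
        if smoothed.max() <= 0.5:
            smoothed = padded
        verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=(dz, dy, dx))
        area = float(measure.mesh_surface_area(verts, faces))
        objects.append(MitoObject(int(lab), vol, area, sphericity(vol, area)))
    if cytoplasm_mask is not None:
        cyto = float(cytoplasm_mask.sum()) * voxel_volume
    elif cytoplasm_volume_um3 is not None:
        cyto = float(cytoplasm_volume_um3)
    else:
        cyto = float(np.prod(labels.shape)) * voxel_volume
    if cyto <= 0:
        raise ValueError("cytoplasmic volume must be positive")
    return MitoMorphology(
        objects=objects,
        density_per_um3=len(objects) / cyto,
        cytoplasm_volume_um3=cyto,
        warnings=warns,
    )


def stack_depth(n_slices: int, step_um: float) -> float:
    """Total optical depth of a confocal stack: n_slices x step (um).

    The convention matches the instrument pairing of 41 slices at a 0.3 um
    step giving a 12.3 um volume.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if step_um <= 0:
        raise ValueError("step must be positive")
    return n_slices * step_um
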