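"""Handcrafted 2D (max-projection) and 3D nuclear morphology features.

These are the feature sets behind the SVM baselines: the classic 2-feature
pair (integrated DAPI intensity + area/volume), its 4-feature combination,
and the extended panels (2D: intensity, area, convex area, bounding-box
area, equivalent diameter, extent, maximum Feret diameter, solidity;
3D: intensity, volume, convex volume, bounding-box volume, surface area,
sphericity).

Geometry is measured on voxel/pixel centers; convex areas/volumes count
lattice points inside the hull (see ``_geometry``). Surface area comes
from a marching-cubes triangulation at level 0.5 with unit spacing of the
lightly smoothed binary mask (Gaussian sigma 0.8, which suppresses the
staircase bias of a raw binary isosurface); sphericity
pi^(1/3) (6V)^(2/3) / A is clamped to 1 with a warning when
discretization pushes it above. All features are in voxel or
pixel units — the SVMs z-score them, so global unit scaling is irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from ._geometry import convex_voxel_count, feret_max

FEATURES_2D = ["intden2d", "area", "convex_area", "bbox_area",
               "equiv_diameter", "extent", "feret_max", "solidity2d"]
FEATURES_3D = ["intden3d", "volume", "convex_volume", "bbox_volume",
               "surface_area", "sphericity"]


def max_project_z(volume: np.ndarray, mask: np.ndarray | None = None):
    """Maximum-intensity projection along Z.

    Returns (image (Y, X), mask2d) where mask2d is the union of per-plane
    mask support (from ``mask`` if given, else from nonzero voxels — crops
    are masked, so background is exactly zero).
    """
    if volume.ndim != 3:
        raise ValueError("expected a (Z, Y, X) volume")
    image = volume.max(axis=0)
    if mask is not None:
        mask2d = np.asarray(mask, dtype=bool).any(axis=0)
    else:
        mask2d = (volume > 0).any(axis=0)
    return image, mask2d


def features_2d(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Extended 2D feature set on a projection image + mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty 2D mask")
    area = int(mask.sum())
    coords = np.argwhere(mask)
    bbox = (coords[:, 0].max() - coords[:, 0].min() + 1) * \
           (coords[:, 1].max() - coords[:, 1].min() + 1)
    convex_area = convex_voxel_count(mask=mask)
    return {
        "intden2d": float(image[mask].sum(dtype=np.float64)),
        "area": float(area),
        "convex_area": float(convex_area),
        "bbox_area": float(bbox),
        "equiv_diameter": float(np.sqrt(4.0 * area / np.pi)),
        "extent": area / float(bbox),
        "feret_max": feret_max(coords),
        "solidity2d": area / float(convex_area),
    }


def features_3d(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Extended 3D feature set on a crop volume + mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty 3D mask")
    v = int(mask.sum())
    coords = np.argwhere(mask)
    bbox = np.prod(coords.max(axis=0) - coords.min(axis=0) + 1)
    # light Gaussian smoothing before meshing suppresses the staircase
    # artifact that otherwise inflates the area of a binary isosurface ~7%
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float32), 2), 0.8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    surface = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / surface)
    if sphericity > 1.0:
        warnings.warn(f"sphericity {sphericity:.4f} > 1 from discretization; "
                      "clamping to 1", stacklevel=2)
        sphericity = 1.0
    return {
        "intden3d": float(volume[mask].sum(dtype=np.float64)),
        "volume": float(v),
        "convex_volume": float(convex_voxel_count(mask=mask)),
        "bbox_volume": float(bbox),
        "surface_area": surface,
        "sphericity": sphericity,
    }


def feature_table(nuclei, feature_set: str = "both") -> pd.DataFrame:
    """Features for a list of (volume, mask) single-nucleus pairs.

    ``feature_set``: '2d', '3d', or 'both'. 2D features are computed on the
    max projection of the masked crop.
    """
    rows = []
    for volume, mask in nuclei:
        row: dict[str, float] = {}
        if feature_set in ("3d", "both"):
            row.update(features_3d(volume, mask))
        if feature_set in ("2d", "both"):
            image, mask2d = max_project_z(volume, mask)
            row.update(features_2d(image, mask2d))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScalingStats:
    """Per-feature mean/SD fitted on training rows only."""

    mean: pd.Series
    sd: pd.Series


def zscore_fit(rows: pd.DataFrame, train_index,
               columns: list[str] | None = None) -> ScalingStats:
    """Fit z-score statistics on the training rows of a feature table.

    Raises (naming the feature) if any feature is constant on the training
    rows — a constant feature cannot be scaled and would be useless anyway.
    """
    train = rows.iloc[train_index]  # positional: callers pass positions/slices
    if columns:
        train = train[columns]
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to fit scaling")
    mean = train.mean()
    sd = train.std(ddof=0)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise ValueError(f"constant feature(s) on training rows: {bad}")
    return ScalingStats(mean=mean, sd=sd)


def zscore_apply(rows: pd.DataFrame, stats: ScalingStats) -> pd.DataFrame:
    """Apply previously fitted scaling to any split (train/val/test)."""
    cols = stats.mean.index
    return (rows[cols] - stats.mean) / stats.sd


__all__ = ["max_project_z", "features_2d", "features_3d", "feature_table",
           "ScalingStats", "zscore_fit", "zscore_apply",
           "FEATURES_2D", "FEATURES_3D"]
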