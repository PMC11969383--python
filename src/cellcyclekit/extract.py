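"""Nucleus extraction: mask QC, per-nucleus quantification, standard crops.

Consumes a 3D integer instance mask (0 = background) plus channel volumes
produced by any external segmenter (or the bundled simulator) and applies
the object-level quality control used throughout the pipeline: objects
touching a tile face are dropped, and objects whose solidity (voxel volume
over convex-hull volume) falls below 0.9 are dropped as doublet/debris
candidates. Surviving nuclei are quantified into one record each and can
be exported as standardized, masked single-nucleus DAPI crops.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import convex_voxel_count

DEFAULT_CROP_XYZ = (150, 150, 90)


def _object_slices(mask: np.ndarray) -> dict[int, tuple[slice, ...]]:
    slices = ndimage.find_objects(mask)
    return {lab + 1: sl for lab, sl in enumerate(slices) if sl is not None}


def _touches_border(sl: tuple[slice, ...], shape: tuple[int, ...]) -> bool:
    # find_objects boxes are tight, so a box touching a face implies a voxel
    # of the object lies on that face
    return any(s.start == 0 or s.stop == dim for s, dim in zip(sl, shape))


def qc_filter_mask(mask: np.ndarray, solidity_min: float = 0.9,
                   drop_border: bool = True) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove border-contacting and low-solidity objects.

    Returns the filtered mask (surviving ids unchanged) and a QC report
    with one row per removed object (columns: label_id, reason, solidity,
    volume_voxels). An empty mask yields an empty report, not an error.
    """
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("mask must be integer-labeled")
    out = mask.copy()
    rows = []
    for label_id, sl in _object_slices(mask).items():
        obj = mask[sl] == label_id
        volume = int(obj.sum())
        if drop_border and _touches_border(sl, mask.shape):
            rows.append({"label_id": label_id, "reason": "border",
                         "solidity": np.nan, "volume_voxels": volume})
            out[sl][obj] = 0
            continue
        sol = volume / convex_voxel_count(mask=obj)
        if sol < solidity_min:
            rows.append({"label_id": label_id, "reason": "solidity",
                         "solidity": sol, "volume_voxels": volume})
            out[sl][obj] = 0
    report = pd.DataFrame(rows, columns=["label_id", "reason", "solidity",
                                         "volume_voxels"])
    return out, report


def quantify(mask: np.ndarray, channels: dict[str, np.ndarray],
             tile_id: str = "tile000", compute_solidity: bool = True) -> pd.DataFrame:
    """One record per labeled object: volume, per-channel aggregate/mean
    intensities, centroid, axis lengths, border flag, solidity.

    ``channels`` maps channel name (e.g. 'dapi', 'gfp', 'rfp') to a volume
    of the same shape as ``mask``. Aggregates are exact float64 sums over
    mask voxels; axis lengths come from the eigen-decomposition of the
    voxel-coordinate covariance (length = 4 * sqrt(eigenvalue), the
    ellipsoid-equivalent convention).
    """
    for name, chan in channels.items():
        if chan.shape != mask.shape:
            raise ValueError(f"channel {name!r} shape {chan.shape} != mask {mask.shape}")
    rows = []
    for label_id, sl in _object_slices(mask).items():
        obj = mask[sl] == label_id
        volume = int(obj.sum())
        if volume == 0:  # impossible with tight boxes; skip defensively
            continue
        coords = np.argwhere(obj) + np.array([s.start for s in sl])
        centroid = coords.mean(axis=0)
        if volume > 1:
            cov = np.cov(coords.T, ddof=0)
            eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
            major, minor = 4.0 * np.sqrt(eigvals[-1]), 4.0 * np.sqrt(eigvals[0])
        else:
            major = minor = 0.0
        row = {
            "tile_id": tile_id, "label_id": label_id,
            "centroid_z": centroid[0], "centroid_y": centroid[1],
            "centroid_x": centroid[2], "volume_voxels": volume,
            "major_axis": major, "minor_axis": minor,
            "touches_border": _touches_border(sl, mask.shape),
            "solidity": volume / convex_voxel_count(mask=obj)
            if compute_solidity else np.nan,
        }
        for name, chan in channels.items():
            agg = float(chan[sl][obj].sum(dtype=np.float64))
            row[f"agg_{name}"] = agg
            row[f"mean_{name}"] = agg / volume
        rows.append(row)
    return pd.DataFrame(rows)


def crop_nucleus(volume: np.ndarray, mask: np.ndarray, label_id: int,
                 crop_shape_xyz: tuple[int, int, int] = DEFAULT_CROP_XYZ
                 ) -> np.ndarray:
    """Masked, centered crop of one nucleus.

    The window of shape (Z, Y, X) = reversed(crop_shape_xyz) is centered on
    the object's centroid (rounded to the nearest integer, ties toward
    negative infinity); regions outside the tile are zero-padded and voxels
    not belonging to ``label_id`` are zeroed, so the crop's integrated
    intensity equals the object's aggregate intensity exactly. Raises if
    any object voxel falls outside the window.
    """
    obj = mask == label_id
    if not obj.any():
        raise KeyError(f"label {label_id} not present in mask")
    out_shape = tuple(reversed(crop_shape_xyz))
    coords = np.argwhere(obj)
    centroid = coords.mean(axis=0)
    center = np.ceil(centroid - 0.5).astype(int)  # ties toward -inf
    out = np.zeros(out_shape, dtype=volume.dtype)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for ax, size in enumerate(out_shape):
        start = center[ax] - size // 2
        lo_obj, hi_obj = coords[:, ax].min(), coords[:, ax].max()
        if lo_obj < start or hi_obj >= start + size:
            raise ValueError(
                f"nucleus {label_id} does not fit in crop window "
                f"{crop_shape_xyz} (XYZ) along axis {ax}")
        s_lo = max(start, 0)
        s_hi = min(start + size, mask.shape[ax])
        src_lo.append(s_lo)
        src_hi.append(s_hi)
        dst_lo.append(s_lo - start)
        dst_hi.append(s_hi - start)
    src = tuple(slice(l, h) for l, h in zip(src_lo, src_hi))
    dst = tuple(slice(l, h) for l, h in zip(dst_lo, dst_hi))
    out[dst] = np.where(obj[src], volume[src], 0)
    return out


def extract_tile(mask: np.ndarray, channels: dict[str, np.ndarray],
                 tile_id: str = "tile000", solidity_min: float = 0.9,
                 drop_border: bool = True,
                 crop_shape_xyz: tuple[int, int, int] = DEFAULT_CROP_XYZ):
    """QC + quantify + crop in one call.

    Returns (records DataFrame, QC report, dict label_id -> DAPI crop).
    """
    filtered, report = qc_filter_mask(mask, solidity_min, drop_border)
    records = quantify(filtered, channels, tile_id=tile_id)
    crops = {int(lid): crop_nucleus(channels["dapi"], filtered, int(lid),
                                    crop_shape_xyz)
             for lid in records["label_id"]}
    return records, report, crops


def write_crops(crops: dict[int, np.ndarray], out_dir: str | Path,
                tile_id: str = "tile000") -> list[Path]:
    """Write crops as single-channel TIFFs named ``{tile}_{label}.tif``."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for label_id, crop in crops.items():
        path = out / f"{tile_id}_{label_id}.tif"
        tifffile.imwrite(path, np.round(crop).astype(np.uint16))
        paths.append(path)
    return paths


__all__ = ["qc_filter_mask", "quantify", "crop_nucleus", "extract_tile",
           "write_crops", "DEFAULT_CROP_XYZ"]
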