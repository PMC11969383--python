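"""Volume preprocessing: crops -> network-ready tensors.

The pipeline per platform: the (Z, Y, X) = (90, 150, 150) masked crop is
block-mean downsampled (epifluorescence: 2x in XY only, to mitigate
anisotropy; confocal: 2x in XYZ, to approach the epifluorescence voxel
size), divided by a single normalization constant (the median over
training crops of each crop's median nonzero intensity), and zero-padded
back to (90, 75, 75). The split is an unstratified, seeded 70/20/10
partition; augmentation is a random in-plane rotation about Z.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .profiles import AcquisitionProfile

FINAL_SHAPE_ZYX = (90, 75, 75)
SPLIT_FRACTIONS = (0.7, 0.2, 0.1)


def downsample(volume: np.ndarray, factors_zyx: tuple[int, int, int]) -> np.ndarray:
    """Block-mean downsampling; axis lengths become ceil(len/factor).

    Block means (rather than strided subsampling) conserve integrated
    intensity up to edge effects; ragged trailing blocks are averaged over
    their actual size.
    """
    out = np.asarray(volume, dtype=np.float64)
    for ax, f in enumerate(factors_zyx):
        if f < 1 or int(f) != f:
            raise ValueError("factors must be positive integers")
        if f == 1:
            continue
        n = out.shape[ax]
        idx = np.arange(0, n, f)
        sums = np.add.reduceat(out, idx, axis=ax)
        counts = np.minimum(idx + f, n) - idx
        shape = [1] * out.ndim
        shape[ax] = len(idx)
        out = sums / counts.reshape(shape)
    return out.astype(np.float32)


def fit_norm(train_crops) -> float:
    """Normalization constant: median over crops of the median nonzero voxel."""
    medians = []
    for i, crop in enumerate(train_crops):
        nz = crop[crop > 0]
        if nz.size == 0:
            raise ValueError(f"crop {i} is all-zero; cannot normalize")
        medians.append(np.median(nz))
    if not medians:
        raise ValueError("no training crops given")
    return float(np.median(medians))


def apply_norm(volume: np.ndarray, norm_constant: float) -> np.ndarray:
    if norm_constant <= 0:
        raise ValueError("norm_constant must be > 0")
    return (np.asarray(volume, dtype=np.float32) / np.float32(norm_constant))


def final_pad(volume: np.ndarray,
              final_shape_zyx: tuple[int, int, int] = FINAL_SHAPE_ZYX) -> np.ndarray:
    """Zero-pad, centered per axis; an odd remainder goes to the trailing side."""
    pads = []
    for have, want in zip(volume.shape, final_shape_zyx):
        if have > want:
            raise ValueError(f"input {volume.shape} exceeds final shape "
                             f"{final_shape_zyx}")
        before = (want - have) // 2
        pads.append((before, want - have - before))
    return np.pad(volume, pads)


def preprocess_crop(crop: np.ndarray, profile: AcquisitionProfile,
                    norm_constant: float,
                    final_shape_zyx: tuple[int, int, int] = FINAL_SHAPE_ZYX
                    ) -> np.ndarray:
    """Downsample (platform factors) -> normalize -> pad. Output (90, 75, 75)."""
    fx, fy, fz = profile.downsample_xyz
    down = downsample(crop, (fz, fy, fx))
    return final_pad(apply_norm(down, norm_constant), final_shape_zyx)


def make_split(ids, fractions: tuple[float, float, float] = SPLIT_FRACTIONS,
               seed: int = 0) -> dict[str, list]:
    """Seeded, unstratified 70/20/10 partition with largest-remainder sizes.

    Returns {'train': [...], 'val': [...], 'test': [...]}; parts are
    disjoint and exhaustive and the result is deterministic per seed.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for k in range(remainder):
        sizes[order[k]] += 1
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    train = shuffled[:sizes[0]]
    val = shuffled[sizes[0]:sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return {"train": train, "val": val, "test": test}


def rotate_z(volume: np.ndarray, angle: float) -> np.ndarray:
    """Rotate each Z-plane about its center by ``angle`` degrees.

    Bilinear interpolation, zero fill, shape preserved; multiples of 90
    degrees are exact (grid maps onto grid).
    """
    if not 0.0 <= angle < 360.0:
        raise ValueError("angle must be in [0, 360)")
    if angle == 0.0:
        return np.asarray(volume, dtype=np.float32).copy()
    return ndimage.rotate(np.asarray(volume, dtype=np.float32), angle,
                          axes=(1, 2), reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


# -------------------------------------------------------------------------
# manifests

def build_manifest(ids, profile: AcquisitionProfile, norm_constant: float,
                   seed: int, source: str | None = None,
                   fractions: tuple[float, float, float] = SPLIT_FRACTIONS,
                   final_shape_zyx: tuple[int, int, int] = FINAL_SHAPE_ZYX) -> dict:
    """Split the ids and record everything needed for a leak-free audit."""
    split = make_split(ids, fractions=fractions, seed=seed)
    return {
        "source": source or profile.name,
        "profile": profile.name,
        "seed": seed,
        "norm_constant": norm_constant,
        "final_shape": list(final_shape_zyx),
        "split": split,
    }


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()


def audit_split(manifest: dict) -> None:
    """Raise unless the three parts are disjoint (no leakage)."""
    split = manifest["split"]
    parts = [set(split[k]) for k in ("train", "val", "test")]
    if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
        raise ValueError("split parts are not disjoint: data leakage")


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


__all__ = ["downsample", "fit_norm", "apply_norm", "final_pad",
           "preprocess_crop", "make_split", "rotate_z", "build_manifest",
           "manifest_hash", "audit_split", "save_manifest", "load_manifest",
           "FINAL_SHAPE_ZYX", "SPLIT_FRACTIONS"]
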