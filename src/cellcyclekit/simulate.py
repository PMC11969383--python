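"""Synthetic Fucci tiles with known per-nucleus ground truth.

The simulator emulates fixed Fucci reporter cells imaged in three channels
(DAPI, GFP = mVenus-hGeminin, RFP = mCherry-hCdt1): nuclei are ellipsoids
with lognormal semi-axes; S/G2 nuclei carry ~1.6x the DAPI density (2N to
4N DNA content) and ~1.3x the volume of G1 nuclei; RFP dominates GFP in G1
draws and the reverse in S/G2. A configurable fraction of non-expressing
cells (both Fucci means below the platform's low-intensity thresholds) and
of extreme-volume objects (doublet-like, 3x volume) is injected so the
ground-truth filters have something to catch. Noise is additive Gaussian
read noise; no optical PSF is simulated (the pipeline never deconvolves).

Expressing cells draw their channel means strictly clear of the exclusion
thresholds (floored at 1.15x threshold) and injected non-expressers
strictly below (0.2-0.8x), so which cells the low-intensity filter must
remove is unambiguous in the truth table. Channel means and DAPI density
are rounded to integers at draw time, so noiseless renders satisfy exact
conservation: integrated DAPI over a nucleus = density x voxel count.

All volumes are stored and indexed (Z, Y, X), matching planewise TIFF
page order; profile metadata (tile shape, voxel size) is given in (X, Y, Z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import AcquisitionProfile

TRUTH_COLUMNS = ["tile_id", "label_id", "phase", "dna_scale", "rfp_mean",
                 "gfp_mean", "volume_voxels", "angle_deg"]


@dataclass(frozen=True)
class SimParams:
    """The simulated world. Defaults are fixed once; see the methods note.

    Each cell carries a latent cycle progression p ~ U(0, 1) (G1 below 0.5,
    S/G2 above). The Fucci channels interpolate geometrically between
    ``fucci_lo`` and ``fucci_hi`` along p (RFP decreasing, GFP increasing),
    and DNA density / volume ramp 1x -> 2x / 1x -> ``sg2_volume_max`` over
    the S-phase interval p in [0.5, 0.9], emulating replication. Expressing
    draws are resampled until their raw GFP/RFP ratio falls outside
    ``ratio_guard`` — the synthetic analogue of omitting cells of
    indistinguishable class along the S-phase border — and their channel
    means are floored at ``floor_factor`` x the platform's low-intensity
    thresholds, so truth flags determine filter outcomes unambiguously.
    """

    radius_um: float = 3.8            # median nuclear semi-axis, physical
    radius_sigma: float = 0.05        # lognormal sigma of the radius draw
    axis_jitter: float = 0.05         # per-axis eccentricity jitter
    sg2_volume_max: float = 1.6       # end-of-cycle volume multiplier
    volume_sigma: float = 0.05
    dna_sigma: float = 0.08
    baseline_dapi: float = 3000.0     # 2N median DAPI density, counts/voxel
    fucci_hi: float = 12000.0         # fully accumulated channel mean
    fucci_lo: float = 2800.0          # degraded channel mean
    fucci_sigma: float = 0.12         # per-channel lognormal noise
    ratio_guard: tuple[float, float] = (0.55, 1.65)
    floor_factor: float = 1.15        # expressers stay >= floor_factor x threshold
    nonexpresser_fraction: float = 0.10
    volume_outlier_fraction: float = 0.03
    volume_outlier_factor: float = 8.0
    transition_fraction: float = 0.0  # draws inside the ratio band


DEFAULT_PARAMS = SimParams()


@dataclass
class SimCell:
    """One simulated nucleus and everything the truth table needs."""

    phase: str                        # 'G1' or 'SG2'
    center: tuple[float, float, float] | None   # (z, y, x) voxels; None = unplaced
    semi_axes: tuple[float, float, float]       # (z, y, x) voxels
    z_rotation: float                 # degrees, about Z
    dna_scale: float                  # multiplier of baseline density
    dna_density: int                  # rounded counts/voxel actually rendered
    rfp_mean: int
    gfp_mean: int
    volume_scale: float
    volume_voxels: int                # analytic ellipsoid volume, rounded
    nonexpresser: bool = False
    volume_outlier: bool = False
    transition: bool = False

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.gfp_mean, self.rfp_mean)))


@dataclass
class SyntheticTile:
    """Rendered channels + instance mask + truth table for one tile."""

    dapi: np.ndarray                  # (Z, Y, X) float32
    gfp: np.ndarray
    rfp: np.ndarray
    mask: np.ndarray                  # (Z, Y, X) uint16 instance labels
    truth: pd.DataFrame               # one row per placed cell
    profile: AcquisitionProfile

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"dapi": self.dapi, "gfp": self.gfp, "rfp": self.rfp}


# -------------------------------------------------------------------------
# population draws

def _ramp(p: float, top: float) -> float:
    """1x below p=0.5, linear to ``top`` over S phase [0.5, 0.9], flat after."""
    if p <= 0.5:
        return 1.0
    if p >= 0.9:
        return top
    return 1.0 + (top - 1.0) * (p - 0.5) / 0.4


def _draw_cell(rng: np.random.Generator, profile: AcquisitionProfile,
               phase: str, params: SimParams, kind: str) -> SimCell:
    p = params
    thr_r, thr_g = profile.low_intensity_thresholds
    lo_p, hi_p = (0.0, 0.5) if phase == "G1" else (0.5, 1.0)
    prog = rng.uniform(lo_p, hi_p)
    # Fucci channel means first: expressing draws redraw (progression,
    # noise) jointly until the raw ratio clears the guard band, i.e. the
    # ground-truthable population omits the transition window
    log_hi, log_lo = np.log(p.fucci_hi), np.log(p.fucci_lo)
    if kind == "nonexpresser":
        rfp = int(round(thr_r * rng.uniform(0.2, 0.8)))
        gfp = int(round(thr_g * rng.uniform(0.2, 0.8)))
    elif kind == "transition":
        amp = rng.lognormal((log_hi + log_lo) / 2.0, p.fucci_sigma)
        rfp = int(round(max(amp, p.floor_factor * thr_r)))
        gfp = int(round(rfp * rng.uniform(0.95, 1.05)))
    else:
        lo_g, hi_g = p.ratio_guard
        for _ in range(500):
            prog = rng.uniform(lo_p, hi_p)
            rfp = np.exp(log_hi + (log_lo - log_hi) * prog
                         + rng.normal(0.0, p.fucci_sigma))
            gfp = np.exp(log_lo + (log_hi - log_lo) * prog
                         + rng.normal(0.0, p.fucci_sigma))
            rfp = max(rfp, p.floor_factor * thr_r)
            gfp = max(gfp, p.floor_factor * thr_g)
            if not lo_g < gfp / rfp < hi_g:
                break
        else:  # pragma: no cover - over half the cycle clears the guard
            raise RuntimeError("could not draw an expressing cell outside "
                               "the ratio guard band")
        rfp, gfp = int(round(rfp)), int(round(gfp))
    # geometry: physical radius -> per-axis voxel semi-axes
    jit = rng.lognormal(0.0, p.axis_jitter, size=3)
    if kind == "volume_outlier":
        # doublet/clump-like object: a tight draw around factor x baseline,
        # independent of cycle stage, so it is categorically abnormal
        r_um = p.radius_um * rng.lognormal(0.0, 0.02)
        vol_scale = p.volume_outlier_factor * rng.lognormal(0.0, 0.05)
    else:
        r_um = p.radius_um * rng.lognormal(0.0, p.radius_sigma)
        vol_scale = _ramp(prog, p.sg2_volume_max) * rng.lognormal(0.0, p.volume_sigma)
    lin = vol_scale ** (1.0 / 3.0)
    vx, vy, vz = profile.voxel_nm
    r_nm = r_um * 1000.0
    semi = (r_nm * lin * jit[0] / vz, r_nm * lin * jit[1] / vy, r_nm * lin * jit[2] / vx)
    volume = int(round(4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2]))
    # DNA content: 2N -> 4N through S
    dna_scale = _ramp(prog, 2.0) * rng.lognormal(0.0, p.dna_sigma)
    density = int(round(p.baseline_dapi * dna_scale))
    return SimCell(phase=phase, center=None, semi_axes=semi,
                   z_rotation=float(rng.uniform(0.0, 360.0)),
                   dna_scale=float(dna_scale), dna_density=density,
                   rfp_mean=rfp, gfp_mean=gfp, volume_scale=float(vol_scale),
                   volume_voxels=volume,
                   nonexpresser=kind == "nonexpresser",
                   volume_outlier=kind == "volume_outlier",
                   transition=kind == "transition")


def sample_measurements(n: int, profile: AcquisitionProfile,
                        class_prior: float = 0.54, rng_seed: int = 0,
                        params: SimParams = DEFAULT_PARAMS) -> list[SimCell]:
    """Draw ``n`` cells (phases, geometry, intensities) without placement.

    ``class_prior`` is the probability of G1 (default 0.54, matching the
    published epifluorescence label balance 2,203 G1 / 1,873 S-G2).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= class_prior <= 1.0:
        raise ValueError("class_prior must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    # exact injected counts (the stated fractions are proportions of the
    # population, not per-cell probabilities), shuffled into random slots
    n_nonexp = int(round(params.nonexpresser_fraction * n))
    n_volout = int(round(params.volume_outlier_fraction * n))
    n_trans = int(round(params.transition_fraction * n))
    if n_nonexp + n_volout + n_trans > n:
        raise ValueError("injected fractions exceed the population")
    kinds = (["nonexpresser"] * n_nonexp + ["volume_outlier"] * n_volout
             + ["transition"] * n_trans
             + ["normal"] * (n - n_nonexp - n_volout - n_trans))
    rng.shuffle(kinds)
    cells = []
    for kind in kinds:
        phase = "G1" if rng.random() < class_prior else "SG2"
        cells.append(_draw_cell(rng, profile, phase, params, kind))
    return cells


def sample_cells(n: int, profile: AcquisitionProfile, class_prior: float = 0.54,
                 rng_seed: int = 0, border_fraction: float = 0.0,
                 params: SimParams = DEFAULT_PARAMS,
                 max_tries: int = 500) -> list[SimCell]:
    """Draw and place ``n`` non-overlapping cells in the profile's tile.

    Placement keeps axis-aligned bounding boxes disjoint (a sufficient
    condition for disjoint ellipsoids). When ``border_fraction`` > 0, that
    fraction of cells is deliberately centered on a lateral tile face so
    the border-QC filter has work to do. Raises if the requested density
    cannot be placed within ``max_tries`` attempts per cell.
    """
    cells = sample_measurements(n, profile, class_prior, rng_seed, params)
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 1)).generate_state(1)[0])
    nz, ny, nx = profile.tile_shape_zyx
    boxes: list[tuple] = []
    n_border = int(round(border_fraction * n))
    for i, cell in enumerate(cells):
        az, ay, ax = cell.semi_axes
        rxy = max(ay, ax)
        on_border = i < n_border
        for attempt in range(max_tries):
            if on_border:
                axis = rng.integers(2)  # 0: y face, 1: x face
                cy = 0.0 if axis == 0 else rng.uniform(rxy + 1, ny - rxy - 2)
                cx = 0.0 if axis == 1 else rng.uniform(rxy + 1, nx - rxy - 2)
                cz = rng.uniform(az + 1, nz - az - 2)
            else:
                cz = rng.uniform(az + 1, nz - az - 2)
                cy = rng.uniform(rxy + 1, ny - rxy - 2)
                cx = rng.uniform(rxy + 1, nx - rxy - 2)
            box = (cz - az - 1, cz + az + 1, cy - rxy - 1, cy + rxy + 1,
                   cx - rxy - 1, cx + rxy + 1)
            if all(box[0] > b[1] or box[1] < b[0] or box[2] > b[3] or box[3] < b[2]
                   or box[4] > b[5] or box[5] < b[4] for b in boxes):
                boxes.append(box)
                cell.center = (cz, cy, cx)
                break
        else:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n} after {max_tries} tries: "
                f"tile {profile.tile_shape} is too dense for ~{n} nuclei of "
                f"semi-axes {tuple(round(s, 1) for s in cell.semi_axes)} voxels")
    return cells


# -------------------------------------------------------------------------
# rendering

def _ellipsoid_membership(shape_zyx: tuple[int, int, int], cell: SimCell):
    """Voxel membership of one (rotated) ellipsoid, clipped to the volume.

    Returns (z-slice, y-slice, x-slice, boolean block).
    """
    nz, ny, nx = shape_zyx
    cz, cy, cx = cell.center  # type: ignore[misc]
    az, ay, ax = cell.semi_axes
    rxy = max(ay, ax)
    z0, z1 = max(int(np.floor(cz - az)) - 1, 0), min(int(np.ceil(cz + az)) + 2, nz)
    y0, y1 = max(int(np.floor(cy - rxy)) - 1, 0), min(int(np.ceil(cy + rxy)) + 2, ny)
    x0, x1 = max(int(np.floor(cx - rxy)) - 1, 0), min(int(np.ceil(cx + rxy)) + 2, nx)
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    t = np.deg2rad(cell.z_rotation)
    dx, dy, dz = xx - cx, yy - cy, zz - cz
    xr = dx * np.cos(t) + dy * np.sin(t)
    yr = -dx * np.sin(t) + dy * np.cos(t)
    member = (xr / ax) ** 2 + (yr / ay) ** 2 + (dz / az) ** 2 <= 1.0
    return slice(z0, z1), slice(y0, y1), slice(x0, x1), member


def render_tile(cells: list[SimCell], profile: AcquisitionProfile,
                noise_sd: float = 30.0, rng_seed: int = 0,
                background: float = 0.0, tile_id: str = "tile000") -> SyntheticTile:
    """Render placed cells into 3 channels + instance mask + truth table.

    Noiseless voxels inside cell ``k`` hold exactly (dna_density,
    gfp_mean, rfp_mean); Gaussian read noise (sd ``noise_sd``) and a flat
    ``background`` offset are then added to every voxel and the result is
    clipped to the profile's bit-depth range. Mask ids are 1..n in input
    order. Raises on overlapping cells (placement should prevent them).
    """
    shape = profile.tile_shape_zyx
    dapi = np.zeros(shape, dtype=np.float32)
    gfp = np.zeros(shape, dtype=np.float32)
    rfp = np.zeros(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint16)
    rows = []
    for idx, cell in enumerate(cells, start=1):
        if cell.center is None:
            raise ValueError(f"cell {idx} has no placement; run sample_cells first")
        zs, ys, xs, member = _ellipsoid_membership(shape, cell)
        if member.sum() == 0:
            raise ValueError(f"cell {idx} renders to zero voxels")
        sub = mask[zs, ys, xs]
        if np.any(sub[member]):
            raise ValueError(f"cell {idx} overlaps a previously rendered cell")
        sub[member] = idx
        mask[zs, ys, xs] = sub
        for chan, value in ((dapi, cell.dna_density), (gfp, cell.gfp_mean),
                            (rfp, cell.rfp_mean)):
            block = chan[zs, ys, xs]
            block[member] = value
            chan[zs, ys, xs] = block
        rows.append({
            "tile_id": tile_id, "label_id": idx, "phase": cell.phase,
            "dna_scale": cell.dna_scale, "dna_density": cell.dna_density,
            "rfp_mean": cell.rfp_mean, "gfp_mean": cell.gfp_mean,
            "volume_voxels": int(member.sum()), "angle_deg": cell.angle_deg,
            "nonexpresser": cell.nonexpresser,
            "volume_outlier": cell.volume_outlier, "transition": cell.transition,
        })
    if noise_sd > 0.0 or background != 0.0:
        rng = np.random.default_rng(rng_seed)
        top = float(profile.max_intensity)
        for chan in (dapi, gfp, rfp):
            noise = rng.normal(background, noise_sd, size=shape) if noise_sd > 0 \
                else background
            np.clip(chan + noise, 0.0, top, out=chan)
    truth = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=TRUTH_COLUMNS + ["dna_density", "nonexpresser", "volume_outlier",
                                 "transition"])
    return SyntheticTile(dapi=dapi, gfp=gfp, rfp=rfp, mask=mask, truth=truth,
                         profile=profile)


# -------------------------------------------------------------------------
# dataset generation (files on disk)

def generate_dataset(n_tiles: int, profile: AcquisitionProfile,
                     out_dir: str | Path, rng_seed: int = 0,
                     cells_per_tile: int = 8, noise_sd: float = 30.0,
                     border_fraction: float = 0.0,
                     class_prior: float = 0.54,
                     params: SimParams = DEFAULT_PARAMS) -> dict:
    """Write per-tile channel TIFFs, mask TIFFs, a truth CSV and a manifest.

    Re-running with the same seed reproduces identical truth CSV content.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * n_tiles)
    truths = []
    files: list[str] = []
    for i in range(n_tiles):
        tile_id = f"tile{i:03d}"
        cells = sample_cells(cells_per_tile, profile, class_prior=class_prior,
                             rng_seed=int(seeds[2 * i] % 2 ** 31),
                             border_fraction=border_fraction, params=params)
        tile = render_tile(cells, profile, noise_sd=noise_sd,
                           rng_seed=int(seeds[2 * i + 1] % 2 ** 31), tile_id=tile_id)
        for name, chan in tile.channels.items():
            path = out / f"{tile_id}_{name}.tif"
            tifffile.imwrite(path, np.round(chan).astype(np.uint16))
            files.append(path.name)
        mask_path = out / f"{tile_id}_mask.tif"
        tifffile.imwrite(mask_path, tile.mask)
        files.append(mask_path.name)
        truths.append(tile.truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(
        columns=TRUTH_COLUMNS)
    truth_path = out / "truth.csv"
    truth[TRUTH_COLUMNS].to_csv(truth_path, index=False, float_format="%.6f")
    manifest = {
        "seed": rng_seed, "profile": profile.name, "n_tiles": n_tiles,
        "cells_per_tile": cells_per_tile, "noise_sd": noise_sd,
        "axis_order": "ZYX", "files": files, "truth": truth_path.name,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -------------------------------------------------------------------------
# single-nucleus volume presets for the CNN experiments

def render_nucleus(shape_zyx: tuple[int, int, int], semi_axes, density: float,
                   noise_sd: float, rng: np.random.Generator,
                   center=None, z_rotation: float = 0.0):
    """Render one masked single-nucleus crop: background exactly zero,
    Gaussian read noise only on nucleus voxels (clipped at 0).

    Returns (volume float32, mask bool).
    """
    nz, ny, nx = shape_zyx
    if center is None:
        center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    cell = SimCell(phase="G1", center=tuple(center), semi_axes=tuple(semi_axes),
                   z_rotation=z_rotation, dna_scale=1.0, dna_density=int(density),
                   rfp_mean=0, gfp_mean=0, volume_scale=1.0, volume_voxels=0)
    zs, ys, xs, member = _ellipsoid_membership(shape_zyx, cell)
    vol = np.zeros(shape_zyx, dtype=np.float32)
    block = vol[zs, ys, xs]
    values = np.full(int(member.sum()), float(density))
    if noise_sd > 0:
        values = np.maximum(values + rng.normal(0.0, noise_sd, size=values.size), 0.0)
    block[member] = values
    vol[zs, ys, xs] = block
    mask = np.zeros(shape_zyx, dtype=bool)
    mb = mask[zs, ys, xs]
    mb[member] = True
    mask[zs, ys, xs] = mb
    return vol, mask


def easy_nuclei(n: int, shape_zyx: tuple[int, int, int] = (16, 16, 16),
                rng_seed: int = 0, noise_sd: float = 60.0,
                baseline: float = 3000.0, g1_prior: float = 0.54):
    """The 'easy' preset: strongly separated classes on a continuous cycle.

    A latent cycle angle theta is drawn uniformly in [8, 38] deg for G1 and
    [52, 82] deg for S/G2 (the gap at 45 deg mirrors the removal of
    transition cells from the real ground truth). DAPI density ramps 1x to
    2x and volume 1x to 1.6x monotonically in theta, emulating 2N -> 4N
    replication, so both the binary label and theta itself are recoverable
    from the DAPI volume alone.

    Returns (volumes (n,1,Z,Y,X) float32, labels (n,) int 1=S/G2,
    theta_deg (n,) float, truth DataFrame).
    """
    rng = np.random.default_rng(rng_seed)
    nz, ny, nx = shape_zyx
    base_xy = 0.26 * min(ny, nx)   # ~4.2 voxels at 16^3
    base_z = 0.22 * nz
    vols = np.zeros((n, 1) + tuple(shape_zyx), dtype=np.float32)
    labels = np.zeros(n, dtype=np.int64)
    thetas = np.zeros(n, dtype=np.float64)
    rows = []
    for i in range(n):
        is_g1 = rng.random() < g1_prior
        theta = rng.uniform(8.0, 38.0) if is_g1 else rng.uniform(52.0, 82.0)
        prog = (theta - 8.0) / 74.0
        density = baseline * (1.0 + prog) * rng.lognormal(0.0, 0.03)
        lin = (1.0 + 0.6 * prog) ** (1.0 / 3.0) * rng.lognormal(0.0, 0.02)
        semi = (base_z * lin, base_xy * lin * rng.lognormal(0.0, 0.02),
                base_xy * lin * rng.lognormal(0.0, 0.02))
        center = ((nz - 1) / 2.0 + rng.uniform(-0.6, 0.6),
                  (ny - 1) / 2.0 + rng.uniform(-0.6, 0.6),
                  (nx - 1) / 2.0 + rng.uniform(-0.6, 0.6))
        vol, mask = render_nucleus(shape_zyx, semi, density, noise_sd, rng,
                                   center=center,
                                   z_rotation=float(rng.uniform(0, 360)))
        vols[i, 0] = vol
        labels[i] = 0 if is_g1 else 1
        thetas[i] = theta
        rows.append({"phase": "G1" if is_g1 else "SG2", "theta_deg": theta,
                     "dna_density": density, "volume_voxels": int(mask.sum())})
    return vols, labels, thetas, pd.DataFrame(rows)


def stress_nuclei(n: int, shape_zyx: tuple[int, int, int] = (24, 32, 32),
                  rng_seed: int = 0, noise_sd: float = 30.0,
                  baseline: float = 3000.0, g1_prior: float = 0.5):
    """The anisotropy-stress preset for the 2D-vs-3D feature comparison.

    Both classes share the same lateral (XY) semi-axis distribution, so the
    projected area carries no class signal; S/G2 nuclei are elongated 1.5x
    along Z (volume ratio 1.5, hidden from any Z-projection) and carry a
    DAPI density only modestly higher (1.25x median) with wide overlap
    (sigma_log 0.18). 3D features therefore see density x volume while 2D
    projections see mostly density.

    Returns (list of (volume, mask), labels array 1=S/G2, truth DataFrame).
    """
    rng = np.random.default_rng(rng_seed)
    nz, ny, nx = shape_zyx
    out = []
    labels = np.zeros(n, dtype=np.int64)
    rows = []
    for i in range(n):
        is_g1 = rng.random() < g1_prior
        a_xy1 = 6.5 * rng.lognormal(0.0, 0.06)
        a_xy2 = 6.5 * rng.lognormal(0.0, 0.06)
        a_z = (4.0 if is_g1 else 6.0) * rng.lognormal(0.0, 0.08)
        density = baseline * (1.0 if is_g1 else 1.25) * rng.lognormal(0.0, 0.18)
        center = ((nz - 1) / 2.0 + rng.uniform(-0.5, 0.5),
                  (ny - 1) / 2.0 + rng.uniform(-0.5, 0.5),
                  (nx - 1) / 2.0 + rng.uniform(-0.5, 0.5))
        vol, mask = render_nucleus(shape_zyx, (a_z, a_xy1, a_xy2), density,
                                   noise_sd, rng, center=center,
                                   z_rotation=float(rng.uniform(0, 360)))
        out.append((vol, mask))
        labels[i] = 0 if is_g1 else 1
        rows.append({"phase": "G1" if is_g1 else "SG2", "dna_density": density,
                     "a_z": a_z, "a_xy": (a_xy1 + a_xy2) / 2,
                     "volume_voxels": int(mask.sum())})
    return out, labels, pd.DataFrame(rows)


__all__ = [
    "SimParams", "DEFAULT_PARAMS", "SimCell", "SyntheticTile", "TRUTH_COLUMNS",
    "sample_measurements", "sample_cells", "render_tile", "generate_dataset",
    "render_nucleus", "easy_nuclei", "stress_nuclei",
]
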