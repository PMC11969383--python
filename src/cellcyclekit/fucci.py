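"""Fucci-based ground-truth labels for G1 vs S/G2, and the cycle angle.

The Fucci2a reporter expresses mCherry-hCdt1 (RFP, accumulates in G1) and
mVenus-hGeminin (GFP, accumulates in S/G2). A segmented nucleus with mean
channel intensities muR, muG and voxel count V is excluded from the ground
truth if it meets any of three criteria, applied in this order:

1. low intensity (non-expressing): muR < muR_min  or  muG < muG_min,
   with platform-specific thresholds (epifluorescence 1,500 / 2,200;
   confocal 700 / 2,000), strict inequalities;
2. ratio (transitioning between phases): 0.9 < muG' / muR' < 1.1 on
   channel-normalized means, both bounds strict;
3. abnormal volume: |V - muV| > 2.5 sigmaV (strict), with muV/sigmaV
   computed over the expressing population.

Survivors are labeled G1 if aggregate R > G, S/G2 if R < G (an exact tie
raises: it is unreachable after the ratio filter under equal normalizers).
The continuous target is theta = atan2(G, R) in degrees in [0, 90]: low
theta is G1-like, high theta S/G2-like, with 45 deg as the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import AcquisitionProfile

RATIO_BAND = (0.9, 1.1)
VOLUME_SD_LIMIT = 2.5
ANGLE_BOUNDARY = 45.0


@dataclass(frozen=True)
class VolumeStats:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def low_intensity_filter(mu_r: float, mu_g: float,
                         profile: AcquisitionProfile) -> bool:
    """True (= exclude) iff either mean falls strictly below its threshold."""
    thr_r, thr_g = profile.low_intensity_thresholds
    return bool(mu_r < thr_r or mu_g < thr_g)


def ratio_filter(mu_r: float, mu_g: float,
                 channel_norms: tuple[float, float]) -> bool:
    """True (= exclude) iff 0.9 < muG'/muR' < 1.1 on normalized means.

    ``channel_norms`` is (normR, normG), both strictly positive. Cells with
    normalized muR of zero are never excluded by this filter.
    """
    norm_r, norm_g = channel_norms
    if norm_r <= 0 or norm_g <= 0:
        raise ValueError("channel normalizers must be strictly positive")
    mu_r_n = mu_r / norm_r
    if mu_r_n == 0:
        return False
    ratio = (mu_g / norm_g) / mu_r_n
    lo, hi = RATIO_BAND
    return bool(lo < ratio < hi)


def volume_filter(v: float, stats: VolumeStats) -> bool:
    """True (= exclude) iff |V - muV| > 2.5 sigmaV (strict)."""
    return bool(abs(v - stats.mu) > VOLUME_SD_LIMIT * stats.sigma)


def assign_label(r: float, g: float) -> str:
    """'G1' iff R > G, 'SG2' iff R < G; an exact tie raises."""
    if r > g:
        return "G1"
    if r < g:
        return "SG2"
    raise ValueError("ambiguous label: R == G (should be excluded upstream)")


def compute_angle(r: float, g: float) -> float:
    """theta = atan2(G, R) in degrees; in [0, 90] for nonnegative inputs."""
    if r == 0 and g == 0:
        raise ValueError("angle undefined for R = G = 0")
    return float(np.degrees(np.arctan2(g, r)))


def binarize_angle(theta: float, boundary: float = ANGLE_BOUNDARY) -> str:
    """'SG2' iff theta > boundary, 'G1' iff theta < boundary; tie raises."""
    if theta > boundary:
        return "SG2"
    if theta < boundary:
        return "G1"
    raise ValueError(f"theta == boundary ({boundary} deg): tie is excluded upstream")


def label_dataset(records: pd.DataFrame, profile: AcquisitionProfile,
                  channel_norms: tuple[float, float] | None = None,
                  volume_stats: VolumeStats | None = None
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three exclusion filters in order and label the survivors.

    ``records`` needs columns ``mean_rfp``, ``mean_gfp``, ``volume_voxels``
    (as produced by ``extract.quantify``); other columns pass through.
    Filters run in the fixed order low-intensity -> ratio -> volume and the
    recorded ``reason`` is the first match. Unless given, channel
    normalizers default to each channel's population mean over the input
    (QC-passing) rows (a scale-matching statistic that stays stable when
    the ratio distribution is bimodal with a sparse middle, as Fucci data
    are), and volume statistics are computed over cells that passed the
    low-intensity filter (expressing cells).

    Returns (labeled copy with columns status/reason/theta_deg, summary
    counts per reason and class).
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    df = records.copy()
    mu_r = df["mean_rfp"].to_numpy(dtype=float)
    mu_g = df["mean_gfp"].to_numpy(dtype=float)
    vol = df["volume_voxels"].to_numpy(dtype=float)
    thr_r, thr_g = profile.low_intensity_thresholds

    low = (mu_r < thr_r) | (mu_g < thr_g)

    if channel_norms is None:
        channel_norms = (float(np.mean(mu_r)), float(np.mean(mu_g)))
    norm_r, norm_g = channel_norms
    if norm_r <= 0 or norm_g <= 0:
        raise ValueError("channel normalizers must be strictly positive")
    mu_r_n = mu_r / norm_r
    mu_g_n = mu_g / norm_g
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mu_r_n > 0, mu_g_n / np.where(mu_r_n > 0, mu_r_n, 1.0), np.inf)
    in_band = (ratio > RATIO_BAND[0]) & (ratio < RATIO_BAND[1])

    if volume_stats is None:
        expressing = vol[~low]
        if expressing.size == 0:
            volume_stats = VolumeStats(mu=float("nan"), sigma=0.0)
        else:
            volume_stats = VolumeStats(mu=float(expressing.mean()),
                                       sigma=float(expressing.std(ddof=0)))
    vol_out = np.abs(vol - volume_stats.mu) > VOLUME_SD_LIMIT * volume_stats.sigma
    if np.isnan(volume_stats.mu):
        vol_out = np.ones_like(low)

    reason = np.full(len(df), "none", dtype=object)
    reason[vol_out] = "volume"
    reason[in_band] = "ratio"
    reason[low] = "low_intensity"   # order: first matching filter wins

    status = np.full(len(df), "excluded", dtype=object)
    survivors = reason == "none"
    # aggregate R vs G reduces to mean R vs mean G (V cancels)
    status[survivors & (mu_r > mu_g)] = "G1"
    status[survivors & (mu_r < mu_g)] = "SG2"
    tie = survivors & (mu_r == mu_g)
    if tie.any():
        raise ValueError(
            f"ambiguous label (R == G) for rows {np.where(tie)[0].tolist()}; "
            "ties should be unreachable after the ratio filter")

    total = mu_r + mu_g
    theta = np.full(len(df), np.nan)
    ok = total > 0
    theta[ok] = np.degrees(np.arctan2(mu_g[ok], mu_r[ok]))

    df["status"] = status
    df["reason"] = reason
    df["theta_deg"] = theta
    summary = {
        "input": int(len(df)),
        "low_intensity": int((reason == "low_intensity").sum()),
        "ratio": int((reason == "ratio").sum()),
        "volume": int((reason == "volume").sum()),
        "excluded": int((status == "excluded").sum()),
        "G1": int((status == "G1").sum()),
        "SG2": int((status == "SG2").sum()),
    }
    return df, summary


__all__ = ["VolumeStats", "low_intensity_filter", "ratio_filter",
           "volume_filter", "assign_label", "compute_angle", "binarize_angle",
           "label_dataset", "RATIO_BAND", "VOLUME_SD_LIMIT", "ANGLE_BOUNDARY"]
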