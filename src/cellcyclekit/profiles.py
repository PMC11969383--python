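"""Acquisition profiles: the two imaging platforms the pipeline supports.

A profile bundles everything downstream stages need to know about how a
dataset was acquired: voxel size (hence anisotropy), tile geometry, camera
bit depth, the platform-specific low-intensity thresholds used by the
Fucci ground-truth filters, and the platform-specific downsampling factors
used by volume preprocessing.

Voxel sizes follow the two study platforms: widefield epifluorescence at
188 x 188 x 500 nm (14-bit camera) and spinning-disk confocal at
183 x 183 x 200 nm (16-bit camera). Tile shapes here are simulator
defaults, not instrument constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionProfile:
    """Imaging-platform metadata.

    Axis conventions: ``voxel_nm``, ``tile_shape`` and ``downsample_xyz``
    are given in (X, Y, Z) order to match how microscope metadata is
    usually written; all in-memory volumes are indexed (Z, Y, X).
    """

    name: str
    voxel_nm: tuple[float, float, float]
    tile_shape: tuple[int, int, int]
    bit_depth: int
    low_intensity_thresholds: tuple[float, float]  # (muR_min, muG_min)
    downsample_xyz: tuple[int, int, int] = (2, 2, 1)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_nm):
            raise ValueError("voxel_nm must be strictly positive")
        if any(s < 64 for s in self.tile_shape):
            raise ValueError("tile_shape dims must each be >= 64")
        if self.bit_depth not in (14, 16):
            raise ValueError("bit_depth must be 14 or 16")
        if any(t < 0 for t in self.low_intensity_thresholds):
            raise ValueError("low-intensity thresholds must be >= 0")

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def tile_shape_zyx(self) -> tuple[int, int, int]:
        x, y, z = self.tile_shape
        return (z, y, x)


EPIFLUORESCENCE = AcquisitionProfile(
    name="epifluorescence",
    voxel_nm=(188.0, 188.0, 500.0),
    tile_shape=(192, 192, 64),
    bit_depth=14,
    low_intensity_thresholds=(1500.0, 2200.0),
    downsample_xyz=(2, 2, 1),
)

CONFOCAL = AcquisitionProfile(
    name="confocal",
    voxel_nm=(183.0, 183.0, 200.0),
    tile_shape=(192, 192, 64),
    bit_depth=16,
    low_intensity_thresholds=(700.0, 2000.0),
    downsample_xyz=(2, 2, 2),
)

_PROFILES = {
    "epifluorescence": EPIFLUORESCENCE,
    "epi": EPIFLUORESCENCE,
    "confocal": CONFOCAL,
}


def get_profile(name: str) -> AcquisitionProfile:
    """Look up a profile by name ('epi'/'epifluorescence' or 'confocal')."""
    try:
        return _PROFILES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; choose from "
                       f"{sorted(set(p.name for p in _PROFILES.values()))}") from None


__all__ = ["AcquisitionProfile", "EPIFLUORESCENCE", "CONFOCAL", "get_profile"]
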