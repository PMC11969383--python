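"""Mask QC, per-nucleus quantification and standardized crops."""

import numpy as np
import pandas as pd
import pytest

from cellcyclekit import extract as ex
from conftest import make_ellipsoid, make_sphere
from oracles import halfspace_convex_count


def embed(obj, shape=(24, 24, 24), offset=(4, 4, 4), label=1):
    mask = np.zeros(shape, dtype=np.int32)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, obj.shape))
    mask[sl][obj] = label
    return mask


class TestQcFilter:
    def test_border_cuboid_removed(self):
        mask = np.zeros((10, 10, 10), dtype=np.int32)
        mask[2:5, 2:5, 0:4] = 1  # flush against the X=0 face
        out, report = ex.qc_filter_mask(mask)
        assert out.sum() == 0
        assert report.reason.tolist() == ["border"]

    def test_centered_sphere_retained(self):
        mask = embed(make_sphere(8), shape=(30, 30, 30), offset=(4, 4, 4))
        out, report = ex.qc_filter_mask(mask)
        assert len(report) == 0
        assert (out == mask).all()

    def test_u_shape_removed_by_solidity(self):
        # two 3x3x9 bars joined by a 3x3x3 bridge: strongly concave
        u = np.zeros((9, 3, 9), dtype=bool)
        u[0:3, :, :] = True
        u[6:9, :, :] = True
        u[3:6, :, 0:3] = True
        mask = embed(u, shape=(15, 9, 15), offset=(3, 3, 3))
        n = u.sum()
        hull = halfspace_convex_count(u)
        assert n / hull < 0.9  # brute-force oracle confirms the fixture
        out, report = ex.qc_filter_mask(mask)
        assert report.reason.tolist() == ["solidity"]
        assert report.solidity.iloc[0] == pytest.approx(n / hull)
        assert out.sum() == 0

    def test_empty_mask_ok(self):
        out, report = ex.qc_filter_mask(np.zeros((5, 5, 5), dtype=np.int32))
        assert out.sum() == 0 and len(report) == 0

    def test_monotone_in_solidity_threshold(self, small_tile):
        mask = small_tile.mask.astype(np.int32)
        survivors = []
        for smin in (0.5, 0.9, 0.99, 1.01):
            out, _ = ex.qc_filter_mask(mask, solidity_min=smin)
            survivors.append(len(np.unique(out)) - 1)
        assert survivors == sorted(survivors, reverse=True)

    def test_surviving_ids_unchanged(self, small_tile):
        out, report = ex.qc_filter_mask(small_tile.mask.astype(np.int32))
        kept = set(np.unique(out)) - {0}
        removed = set(report.label_id)
        assert kept | removed == set(np.unique(small_tile.mask)) - {0}
        assert not kept & removed


class TestQuantify:
    def test_constant_cube(self):
        mask = np.zeros((14, 14, 14), dtype=np.int32)
        mask[2:12, 2:12, 2:12] = 1
        dapi = np.where(mask > 0, 5.0, 0.0)
        rec = ex.quantify(mask, {"dapi": dapi})
        assert rec.volume_voxels.iloc[0] == 1000
        assert rec.agg_dapi.iloc[0] == 5000.0
        assert rec.mean_dapi.iloc[0] == 5.0

    def test_sphere_axes_symmetric(self):
        mask = embed(make_sphere(7), shape=(26, 26, 26))
        rec = ex.quantify(mask, {})
        assert rec.major_axis.iloc[0] == pytest.approx(rec.minor_axis.iloc[0],
                                                       rel=0.05)

    def test_ellipsoid_axis_ratio(self):
        # semi-axes (12, 8, 8): moment-tensor axis ratio ~ 1.5 within 10%
        mask = embed(make_ellipsoid((12, 8, 8)), shape=(36, 30, 30))
        rec = ex.quantify(mask, {})
        assert rec.major_axis.iloc[0] / rec.minor_axis.iloc[0] == \
            pytest.approx(1.5, rel=0.10)

    def test_aggregate_equals_mean_times_volume(self, noisy_tile):
        rec = ex.quantify(noisy_tile.mask.astype(np.int32), noisy_tile.channels)
        for chan in ("dapi", "gfp", "rfp"):
            np.testing.assert_allclose(rec[f"agg_{chan}"],
                                       rec[f"mean_{chan}"] * rec.volume_voxels)

    def test_relabeling_permutes_rows_only(self, small_tile):
        mask = small_tile.mask.astype(np.int32)
        perm = mask.copy()
        perm[mask == 1], perm[mask == 2] = 2, 1
        a = ex.quantify(mask, {"dapi": small_tile.dapi}).set_index("label_id")
        b = ex.quantify(perm, {"dapi": small_tile.dapi}).set_index("label_id")
        cols = ["volume_voxels", "agg_dapi", "centroid_z"]
        pd.testing.assert_frame_equal(
            a.loc[[1, 2], cols], b.loc[[2, 1], cols].rename(index={2: 1, 1: 2}))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            ex.quantify(np.zeros((4, 4, 4), dtype=np.int32),
                        {"dapi": np.zeros((4, 4, 5))})


class TestCrop:
    def test_centering_and_shape(self):
        mask = np.zeros((30, 40, 40), dtype=np.int32)
        mask[14:17, 19:22, 19:22] = 1
        vol = np.where(mask > 0, 7.0, 1.0)
        crop = ex.crop_nucleus(vol, mask, 1, crop_shape_xyz=(20, 20, 10))
        assert crop.shape == (10, 20, 20)
        center = crop[5, 10, 10]
        assert center == 7.0
        assert crop.sum() == 7.0 * 27  # background zeroed

    def test_corner_nucleus_zero_padded(self, small_tile):
        # a nucleus whose window extends past the tile is zero-filled
        rec = ex.quantify(small_tile.mask.astype(np.int32),
                          {"dapi": small_tile.dapi})
        for lid in rec.label_id:
            crop = ex.crop_nucleus(small_tile.dapi,
                                   small_tile.mask.astype(np.int32), int(lid))
            assert crop.shape == (90, 150, 150)

    def test_masked_crop_conservation(self, noisy_tile):
        mask = noisy_tile.mask.astype(np.int32)
        rec = ex.quantify(mask, noisy_tile.channels).set_index("label_id")
        for lid in rec.index:
            crop = ex.crop_nucleus(noisy_tile.dapi, mask, int(lid))
            assert crop.sum(dtype=np.float64) == rec.loc[lid, "agg_dapi"]

    def test_too_large_nucleus_raises(self):
        mask = np.zeros((30, 30, 30), dtype=np.int32)
        mask[5:25, 5:25, 5:25] = 3
        with pytest.raises(ValueError, match="3"):
            ex.crop_nucleus(np.ones_like(mask, dtype=float), mask, 3,
                            crop_shape_xyz=(10, 10, 10))

    def test_missing_label_raises(self):
        with pytest.raises(KeyError):
            ex.crop_nucleus(np.zeros((5, 5, 5)),
                            np.zeros((5, 5, 5), dtype=np.int32), 1)


def test_extract_tile_end_to_end(small_tile, tmp_path):
    records, report, crops = ex.extract_tile(
        small_tile.mask.astype(np.int32), small_tile.channels, tile_id="t0")
    assert set(records.label_id) == set(crops)
    assert len(records) + len(report) == small_tile.truth.shape[0]
    paths = ex.write_crops(crops, tmp_path, tile_id="t0")
    assert all(p.exists() for p in paths)
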