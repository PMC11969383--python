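"""Synthetic Fucci tile generator: determinism, conservation, separation."""

import json

import numpy as np
import pandas as pd
import pytest

from cellcyclekit import simulate as sim


class TestSampleCells:
    def test_empty(self, epi):
        assert sim.sample_cells(0, epi, rng_seed=7) == []

    def test_deterministic(self, epi):
        a = sim.sample_cells(10, epi, rng_seed=7)
        b = sim.sample_cells(10, epi, rng_seed=7)
        assert a == b

    def test_class_prior_binomial(self, epi):
        # G1 count should land within 3 binomial SDs of n * prior
        cells = sim.sample_measurements(1000, epi, class_prior=0.54, rng_seed=1)
        g1 = sum(c.phase == "G1" for c in cells)
        sd = np.sqrt(1000 * 0.54 * 0.46)
        assert abs(g1 - 540) <= 3 * sd

    def test_placement_non_overlapping(self, small_tile):
        # rendering would raise on overlap; also check ids are 1..n
        ids = np.unique(small_tile.mask)
        assert list(ids) == list(range(0, 9))

    def test_density_limit_error(self, epi):
        with pytest.raises(RuntimeError, match="dense"):
            sim.sample_cells(500, epi, rng_seed=0)

    def test_bad_args(self, epi):
        with pytest.raises(ValueError):
            sim.sample_measurements(-1, epi)
        with pytest.raises(ValueError):
            sim.sample_measurements(5, epi, class_prior=1.5)


class TestRenderTile:
    def test_empty_tile(self, epi):
        tile = sim.render_tile([], epi, noise_sd=0.0)
        assert tile.mask.sum() == 0
        assert all(c.sum() == 0 for c in tile.channels.values())
        assert len(tile.truth) == 0

    def test_noiseless_conservation_exact(self, small_tile):
        # integrated DAPI over each nucleus == density x voxel count, exactly
        for _, row in small_tile.truth.iterrows():
            m = small_tile.mask == row.label_id
            assert small_tile.dapi[m].sum(dtype=np.float64) == \
                row.dna_density * row.volume_voxels
            assert small_tile.gfp[m].mean(dtype=np.float64) == row.gfp_mean
            assert small_tile.rfp[m].mean(dtype=np.float64) == row.rfp_mean

    def test_mask_channel_consistency(self, small_tile):
        assert np.all(small_tile.dapi[small_tile.mask > 0] > 0)

    def test_sg2_brighter_and_larger(self, epi):
        # population separation: S/G2 mean integrated DAPI and volume exceed G1
        rows = []
        for seed in range(3):
            cells = sim.sample_cells(10, epi, rng_seed=100 + seed)
            tile = sim.render_tile(cells, epi, noise_sd=0.0, rng_seed=seed)
            for _, row in tile.truth.iterrows():
                rows.append((row.phase, row.dna_density * row.volume_voxels,
                             row.volume_voxels))
        df = pd.DataFrame(rows, columns=["phase", "intden", "volume"])
        df = df[~df.volume.gt(df.volume.median() * 4)]  # drop injected outliers
        g = df.groupby("phase").mean()
        assert g.loc["SG2", "intden"] > g.loc["G1", "intden"]
        assert g.loc["SG2", "volume"] > g.loc["G1", "volume"]

    def test_overlap_raises(self, epi):
        cells = sim.sample_cells(2, epi, rng_seed=3)
        cells[1].center = cells[0].center
        with pytest.raises(ValueError, match="overlap"):
            sim.render_tile(cells, epi)

    def test_intensities_within_bit_depth(self, noisy_tile, epi):
        for chan in noisy_tile.channels.values():
            assert chan.min() >= 0
            assert chan.max() <= epi.max_intensity


class TestTruthSemantics:
    def test_angle_matches_channel_means(self, small_tile):
        for _, row in small_tile.truth.iterrows():
            expected = np.degrees(np.arctan2(row.gfp_mean, row.rfp_mean))
            assert row.angle_deg == pytest.approx(expected)

    def test_injected_fractions_exact(self, epi):
        pop = sim.sample_measurements(1000, epi, rng_seed=4)
        assert sum(c.nonexpresser for c in pop) == 100
        assert sum(c.volume_outlier for c in pop) == 30

    def test_nonexpressers_below_thresholds(self, epi):
        pop = sim.sample_measurements(500, epi, rng_seed=8)
        thr_r, thr_g = epi.low_intensity_thresholds
        for c in pop:
            if c.nonexpresser:
                assert c.rfp_mean < thr_r and c.gfp_mean < thr_g
            else:
                assert c.rfp_mean >= thr_r and c.gfp_mean >= thr_g


class TestGenerateDataset:
    def test_manifest_and_conservation(self, tmp_path, epi):
        man = sim.generate_dataset(2, epi, tmp_path, rng_seed=3,
                                   cells_per_tile=4)
        assert len(man["files"]) == 2 * 4  # 3 channels + mask per tile
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert list(truth.columns) == sim.TRUTH_COLUMNS
        assert len(truth) == 8
        assert json.loads((tmp_path / "manifest.json").read_text()) == man

    def test_truth_csv_reproducible(self, tmp_path, epi):
        sim.generate_dataset(2, epi, tmp_path / "a", rng_seed=3, cells_per_tile=4)
        sim.generate_dataset(2, epi, tmp_path / "b", rng_seed=3, cells_per_tile=4)
        assert (tmp_path / "a" / "truth.csv").read_bytes() == \
            (tmp_path / "b" / "truth.csv").read_bytes()

    def test_tiffs_roundtrip(self, tmp_path, epi):
        import tifffile

        sim.generate_dataset(1, epi, tmp_path, rng_seed=5, cells_per_tile=3)
        mask = tifffile.imread(tmp_path / "tile000_mask.tif")
        assert mask.shape == epi.tile_shape_zyx
        assert mask.max() == 3


class TestNucleusPresets:
    def test_easy_preset_separation(self):
        vols, labels, thetas, truth = sim.easy_nuclei(60, rng_seed=0)
        assert vols.shape == (60, 1, 16, 16, 16)
        # theta encodes the class with a gap at 45 degrees
        assert np.all((thetas[labels == 0] < 45) & (thetas[labels == 0] >= 8))
        assert np.all((thetas[labels == 1] > 45) & (thetas[labels == 1] <= 82))
        intden = vols.sum(axis=(1, 2, 3, 4))
        assert intden[labels == 1].mean() > 1.5 * intden[labels == 0].mean()

    def test_stress_preset_projected_area_matched(self):
        nuclei, labels, truth = sim.stress_nuclei(120, rng_seed=1)
        area = np.array([(m.any(axis=0)).sum() for _, m in nuclei])
        vol = np.array([m.sum() for _, m in nuclei])
        # projected area carries almost no class signal; volume does
        a_ratio = area[labels == 1].mean() / area[labels == 0].mean()
        v_ratio = vol[labels == 1].mean() / vol[labels == 0].mean()
        assert 0.95 < a_ratio < 1.05
        assert v_ratio > 1.3

    def test_presets_deterministic(self):
        a = sim.easy_nuclei(10, rng_seed=3)[0]
        b = sim.easy_nuclei(10, rng_seed=3)[0]
        np.testing.assert_array_equal(a, b)
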