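"""Fucci ground-truth labeling: the three filters, labels, and the angle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcyclekit import fucci, simulate as sim
from cellcyclekit.fucci import VolumeStats


class TestLowIntensityFilter:
    @pytest.mark.parametrize("mu_r, mu_g, profile_name, excluded", [
        (1400, 5000, "epi", True),     # below the RFP threshold
        (1500, 2200, "epi", False),    # boundary: strict '<' keeps it
        (5000, 2199, "epi", True),
        (700, 2000, "confocal", False),  # confocal boundary kept
        (699, 5000, "confocal", True),
    ])
    def test_thresholds(self, mu_r, mu_g, profile_name, excluded, epi, confocal):
        profile = epi if profile_name == "epi" else confocal
        assert fucci.low_intensity_filter(mu_r, mu_g, profile) is excluded


class TestRatioFilter:
    @pytest.mark.parametrize("ratio, excluded", [
        (1.0, True), (0.9, False), (1.1, False), (2.0, False), (0.95, True),
    ])
    def test_band(self, ratio, excluded):
        # unit normalizers: the band acts on the raw ratio
        assert fucci.ratio_filter(100.0, 100.0 * ratio, (1.0, 1.0)) is excluded

    def test_normalizers_rescale_the_band(self):
        # muG'/muR' = (300/3) / (100/1) = 1.0 -> excluded
        assert fucci.ratio_filter(100.0, 300.0, (1.0, 3.0)) is True
        assert fucci.ratio_filter(100.0, 300.0, (1.0, 1.0)) is False

    def test_zero_rfp_never_excluded(self):
        assert fucci.ratio_filter(0.0, 50.0, (1.0, 1.0)) is False

    def test_nonpositive_norms_raise(self):
        with pytest.raises(ValueError):
            fucci.ratio_filter(1.0, 1.0, (0.0, 1.0))


class TestVolumeFilter:
    @pytest.mark.parametrize("v, excluded", [
        (1000.0, False),            # V == mu
        (1250.0, False),            # exactly 2.5 SD: strict '>' keeps it
        (1300.0, True),             # 3 SD out
        (700.0, True),
    ])
    def test_sd_rule(self, v, excluded):
        assert fucci.volume_filter(v, VolumeStats(1000.0, 100.0)) is excluded

    def test_degenerate_sd(self):
        assert fucci.volume_filter(5.0, VolumeStats(5.0, 0.0)) is False
        assert fucci.volume_filter(6.0, VolumeStats(5.0, 0.0)) is True


class TestLabelAndAngle:
    def test_assign_label(self):
        assert fucci.assign_label(10, 5) == "G1"
        assert fucci.assign_label(5, 10) == "SG2"
        with pytest.raises(ValueError, match="ambiguous"):
            fucci.assign_label(7, 7)

    @pytest.mark.parametrize("r, g, theta", [
        (1, 1, 45.0), (1, 0, 0.0), (0, 1, 90.0), (3, 4, 53.130),
    ])
    def test_compute_angle(self, r, g, theta):
        assert fucci.compute_angle(r, g) == pytest.approx(theta, abs=1e-3)

    def test_angle_undefined_at_origin(self):
        with pytest.raises(ValueError):
            fucci.compute_angle(0, 0)

    def test_binarize(self):
        assert fucci.binarize_angle(10.0) == "G1"
        assert fucci.binarize_angle(80.0) == "SG2"
        with pytest.raises(ValueError):
            fucci.binarize_angle(45.0)

    @given(r=st.floats(0.1, 1e6), g=st.floats(0.1, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_label_angle_consistency(self, r, g):
        # under equal normalizers: G1 <=> theta < 45 for any surviving cell
        if r == g:
            return
        label = fucci.assign_label(r, g)
        theta = fucci.compute_angle(r, g)
        assert (label == "G1") == (theta < 45.0)


def _table(rows):
    return pd.DataFrame(rows, columns=["mean_rfp", "mean_gfp", "volume_voxels"])


class TestLabelDataset:
    def test_all_below_thresholds(self, epi):
        df = _table([(100, 100, 1000)] * 5)
        labeled, summary = fucci.label_dataset(df, epi)
        assert (labeled.reason == "low_intensity").all()
        assert summary["low_intensity"] == 5

    def test_conservation(self, epi):
        pop = sim.sample_measurements(400, epi, rng_seed=11)
        df = _table([(c.rfp_mean, c.gfp_mean, c.volume_voxels) for c in pop])
        labeled, summary = fucci.label_dataset(df, epi)
        assert summary["G1"] + summary["SG2"] + summary["excluded"] == 400
        assert set(labeled.status) <= {"G1", "SG2", "excluded"}
        assert ((labeled.status == "excluded") == (labeled.reason != "none")).all()

    def test_exclusions_match_simulator_truth(self, epi):
        pop = sim.sample_measurements(500, epi, rng_seed=12)
        df = _table([(c.rfp_mean, c.gfp_mean, c.volume_voxels) for c in pop])
        labeled, _ = fucci.label_dataset(df, epi)
        assert set(np.where(labeled.reason == "low_intensity")[0]) == \
            {i for i, c in enumerate(pop) if c.nonexpresser}
        assert set(np.where(labeled.reason == "volume")[0]) == \
            {i for i, c in enumerate(pop) if c.volume_outlier}

    def test_transition_cells_hit_ratio_filter(self, epi):
        params = sim.SimParams(nonexpresser_fraction=0.0,
                               volume_outlier_fraction=0.0,
                               transition_fraction=0.1)
        pop = sim.sample_measurements(300, epi, rng_seed=13, params=params)
        df = _table([(c.rfp_mean, c.gfp_mean, c.volume_voxels) for c in pop])
        # unit normalizers: transition draws sit at raw ratio ~ 1
        labeled, summary = fucci.label_dataset(df, epi, channel_norms=(1.0, 1.0))
        trans = {i for i, c in enumerate(pop) if c.transition}
        assert set(np.where(labeled.reason == "ratio")[0]) == trans
        assert summary["ratio"] == 30

    def test_order_invariance_of_survivors(self, epi):
        # a cell survives iff it meets no criterion, however filters are ordered
        pop = sim.sample_measurements(300, epi, rng_seed=14)
        df = _table([(c.rfp_mean, c.gfp_mean, c.volume_voxels) for c in pop])
        labeled, _ = fucci.label_dataset(df, epi)
        norms = (df.mean_rfp.mean(), df.mean_gfp.mean())
        low = df.apply(lambda r: fucci.low_intensity_filter(
            r.mean_rfp, r.mean_gfp, epi), axis=1)
        ratio = df.apply(lambda r: fucci.ratio_filter(
            r.mean_rfp, r.mean_gfp, norms), axis=1)
        expressing = df.volume_voxels[~low]
        stats = VolumeStats(expressing.mean(), expressing.std(ddof=0))
        vol = df.volume_voxels.apply(lambda v: fucci.volume_filter(v, stats))
        any_criterion = low | ratio | vol
        assert ((labeled.status == "excluded") == any_criterion).all()

    def test_theta_reported_for_survivors(self, epi):
        pop = sim.sample_measurements(200, epi, rng_seed=15)
        df = _table([(c.rfp_mean, c.gfp_mean, c.volume_voxels) for c in pop])
        labeled, _ = fucci.label_dataset(df, epi)
        surv = labeled[labeled.status != "excluded"]
        assert surv.theta_deg.between(0, 90).all()
        assert ((surv.status == "G1") == (surv.theta_deg < 45)).all()

    def test_empty_table_raises(self, epi):
        with pytest.raises(ValueError):
            fucci.label_dataset(_table([]), epi)
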