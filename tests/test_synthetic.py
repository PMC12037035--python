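"""Generator contracts: determinism, ground-truth oracles, invariants."""

import numpy as np
import pytest
from scipy import ndimage

from fluoquant import synthetic
from fluoquant.synthetic import PlacementError


def count_half_max_components(img: np.ndarray) -> int:
    """Independent oracle: connected components above half of the maximum."""
    if img.max() == 0:
        return 0
    labeled, n = ndimage.label(img > img.max() / 2)
    return n


class TestClusterImage:
    def test_zero_clusters_blank(self):
        scene, truth = synthetic.simulate_cluster_image(0, noise_sd=0, seed=0)
        assert scene.channel("CD20").max() == 0
        assert truth.params["n_clusters"] == 0
        assert truth.derived["centers_um"] == []

    def test_twenty_disjoint_discs(self):
        scene, truth = synthetic.simulate_cluster_image(20, noise_sd=0, seed=1)
        assert count_half_max_components(truth.arrays["clean"]) == 20

    def test_same_seed_identical(self):
        s1, _ = synthetic.simulate_cluster_image(5, noise_sd=3.0, seed=42)
        s2, _ = synthetic.simulate_cluster_image(5, noise_sd=3.0, seed=42)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_impossible_packing_raises(self):
        with pytest.raises(PlacementError):
            synthetic.simulate_cluster_image(
                50, cell_mask_radius_um=2.0, min_separation_um=3.0, seed=0
            )

    def test_truth_area_closed_form(self):
        _, truth = synthetic.simulate_cluster_image(
            7, mean_radius_um=0.4, seed=3
        )
        assert truth.derived["total_area_um2"] == pytest.approx(
            7 * np.pi * 0.4**2
        )


class TestColocPair:
    def test_full_overlap_identical_masks(self):
        scene, truth = synthetic.simulate_coloc_pair(1.0, noise_sd=0, seed=0)
        np.testing.assert_array_equal(
            truth.arrays["mask_a"], truth.arrays["mask_b"]
        )
        np.testing.assert_array_equal(
            scene.channel("CD20"), scene.channel("CD70")
        )

    def test_zero_overlap_disjoint(self):
        _, truth = synthetic.simulate_coloc_pair(0.0, noise_sd=0, seed=0)
        assert not (truth.arrays["mask_a"] & truth.arrays["mask_b"]).any()
        assert truth.derived["pixel_overlap_fraction"] == 0.0

    def test_recorded_overlap_is_pixel_count_ratio(self):
        _, truth = synthetic.simulate_coloc_pair(0.5, noise_sd=0, seed=1)
        a, b = truth.arrays["mask_a"], truth.arrays["mask_b"]
        expected = np.sum(a & b) / np.sum(a | b)
        assert truth.derived["pixel_overlap_fraction"] == pytest.approx(expected)

    def test_deterministic(self):
        s1, _ = synthetic.simulate_coloc_pair(0.5, noise_sd=2.0, seed=9)
        s2, _ = synthetic.simulate_coloc_pair(0.5, noise_sd=2.0, seed=9)
        np.testing.assert_array_equal(s1.data, s2.data)


class TestFrapSeries:
    def test_full_recovery_asymptote_reaches_prebleach(self):
        series, _ = synthetic.simulate_frap_series(
            1.0, tau_s=5.0, acquisition_bleach_rate=0.0, n_post=200, noise_sd=0
        )
        pre_mean = series.roi[: series.bleach_index].mean()
        assert series.roi[-1] == pytest.approx(pre_mean, rel=1e-3)

    def test_immobile_flat_at_depth(self):
        series, _ = synthetic.simulate_frap_series(
            0.0, tau_s=5.0, bleach_depth=0.8, noise_sd=0
        )
        post = series.roi[series.bleach_index:] - series.bg[series.bleach_index:]
        pre = (series.roi - series.bg)[: series.bleach_index].mean()
        np.testing.assert_allclose(post, (1 - 0.8) * pre, rtol=1e-12)

    def test_half_recovery_at_tau_ln2(self):
        # closed form: the ideal curve crosses half of its recovery at tau*ln2
        tau = 2.0
        series, truth = synthetic.simulate_frap_series(
            0.6, tau_s=tau, bleach_depth=0.8, dt_s=0.002, n_post=10000,
            noise_sd=0,
        )
        assert truth.derived["t_half_s"] == pytest.approx(tau * np.log(2))
        t_post = series.t_s[series.bleach_index:] - series.t_s[series.bleach_index]
        y = series.roi[series.bleach_index:] - series.bg[series.bleach_index:]
        y0, y_inf = y[0], y[-1]
        half_idx = np.argmax(y >= y0 + (y_inf - y0) / 2)
        assert t_post[half_idx] == pytest.approx(tau * np.log(2), rel=0.01)


class TestTrajectories:
    def test_stationary(self):
        ts, _ = synthetic.simulate_trajectories(
            3, 50, d_confined_um2s=0, d_active_um2s=0, drift_speed_um_s=0,
            loc_error_um=0, seed=0,
        )
        for track in ts.tracks:
            assert np.ptp(track.xy_um, axis=0).max() == 0

    def test_brownian_msd_slope(self):
        d_true = 0.05
        ts, _ = synthetic.simulate_trajectories(
            200, 100, d_active_um2s=d_true, start_state=1, switch_prob=0,
            drift_speed_um_s=0, loc_error_um=0, seed=7,
        )
        from fluoquant.spt import msd_curve

        slopes = []
        for track in ts.tracks:
            lag, msd = msd_curve(track, ts.dt_s, 4)
            slopes.append(np.polyfit(lag, msd, 1)[0])
        assert np.mean(slopes) / 4 == pytest.approx(d_true, rel=0.1)

    def test_no_switching_stays_confined(self):
        _, truth = synthetic.simulate_trajectories(
            5, 100, switch_prob=0, start_state=0, seed=1
        )
        assert (truth.arrays["states"] == 0).all()

    def test_deterministic(self):
        ts1, _ = synthetic.simulate_trajectories(4, 30, switch_prob=0.1, seed=5)
        ts2, _ = synthetic.simulate_trajectories(4, 30, switch_prob=0.1, seed=5)
        for a, b in zip(ts1.tracks, ts2.tracks):
            np.testing.assert_array_equal(a.xy_um, b.xy_um)


class TestPlaImage:
    def test_zero_spots(self):
        _, truth = synthetic.simulate_pla_image(0, cell_count=3, seed=0)
        assert truth.derived["counts_per_cell"] == [0, 0, 0]

    def test_counts_conserved(self):
        _, truth = synthetic.simulate_pla_image(12, cell_count=3, seed=2)
        assert sum(truth.derived["counts_per_cell"]) == 12

    def test_separated_spots_recoverable(self):
        _, truth = synthetic.simulate_pla_image(9, cell_count=3, seed=3)
        clean = truth.arrays["pla_clean"]
        labeled, n = ndimage.label(clean > clean.max() / 2)
        assert n == 9


class TestSynapseScene:
    def test_unit_ratio_equal_means(self):
        scene, truth = synthetic.simulate_synapse_scene(
            2, enrichment_ratio=1.0, noise_sd=0, seed=0
        )
        cd70 = scene.channel("CD70")
        for contact, membrane in zip(
            truth.arrays["contact_masks"], truth.arrays["b_membranes"]
        ):
            out = membrane & ~contact
            assert cd70[contact].mean() == pytest.approx(cd70[out].mean())

    def test_counts(self):
        _, truth = synthetic.simulate_synapse_scene(
            0, n_free_b_cells=5, seed=0
        )
        assert truth.derived["n_synapses"] == 0
        assert truth.derived["n_b_cells"] == 5

    def test_ratio_oracle_on_truth_masks(self):
        scene, truth = synthetic.simulate_synapse_scene(
            1, enrichment_ratio=2.0, noise_sd=0, seed=1
        )
        cd70 = scene.channel("CD70")
        contact = truth.arrays["contact_masks"][0]
        membrane = truth.arrays["b_membranes"][0]
        out = membrane & ~contact
        assert cd70[contact].mean() / cd70[out].mean() == pytest.approx(2.0)


class TestStampScene:
    def test_unit_enrichment(self):
        scene, truth = synthetic.simulate_stamp_scene(
            on_stamp_enrichment=1.0, noise_sd=0
        )
        rep = scene.channel("CD70")
        mask = truth.arrays["stamp_mask"]
        assert rep[mask].mean() == pytest.approx(rep[~mask].mean())

    def test_disc_diameter_in_pixels(self):
        _, truth = synthetic.simulate_stamp_scene(
            spot_diameter_um=5.0, pitch_um=10.0, pixel_size_um=0.1
        )
        mask = truth.arrays["stamp_mask"]
        labeled, n = ndimage.label(mask)
        widths = []
        for i in range(1, n + 1):
            ys, xs = np.nonzero(labeled == i)
            widths.append(xs.max() - xs.min() + 1)
        assert max(widths) == pytest.approx(50, abs=2)

    def test_enrichment_oracle(self):
        scene, truth = synthetic.simulate_stamp_scene(
            on_stamp_enrichment=3.0, noise_sd=0
        )
        rep = scene.channel("CD70")
        mask = truth.arrays["stamp_mask"]
        assert rep[mask].mean() / rep[~mask].mean() == pytest.approx(3.0)


class TestCalibrationBeads:
    def test_noiseless_proportional(self):
        table, truth = synthetic.simulate_calibration_beads(
            gain=0.02, noise_cv=0
        )
        beads = table[table["kind"] == "bead"]
        np.testing.assert_allclose(
            beads["mfi"].to_numpy(), 0.02 * beads["abc"].to_numpy()
        )

    def test_zero_abc_zero_mfi(self):
        table, _ = synthetic.simulate_calibration_beads(
            abc_values=[0.0, 1000.0, 5000.0], noise_cv=0
        )
        assert table.loc[table["abc"] == 0, "mfi"].iloc[0] == 0.0

    def test_sample_recovery_inverse(self):
        table, truth = synthetic.simulate_calibration_beads(
            sample_abcs=[95_000.0], gain=0.05, noise_cv=0
        )
        sample_mfi = table.loc[table["kind"] == "sample", "mfi"].iloc[0]
        assert sample_mfi / 0.05 == pytest.approx(95_000.0)
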