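import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.feature import peak_local_max

from fluoquant import synthetic
from fluoquant.clusters import (
    ClusterParams,
    calibrate_molecules,
    count_pla_spots,
    detect_clusters,
    fit_calibration,
    molecules_per_cluster,
)
from fluoquant.io_core import ImageScene


NOISELESS = ClusterParams(otsu_offset_percent=0.0, smooth_sigma_px=0.0)


class TestDetectClusters:
    def test_recovers_simulated_count(self):
        scene, _ = synthetic.simulate_cluster_image(20, noise_sd=0, seed=1)
        _, table = detect_clusters(scene, "CD20", NOISELESS)
        assert len(table) == 20

    def test_blank_image_zero_records(self):
        scene = ImageScene(np.zeros((1, 64, 64)), ["CD20"], 0.05)
        mask, table = detect_clusters(scene, "CD20")
        assert len(table) == 0
        assert mask.n_regions == 0

    def test_nonfinite_rejected(self):
        data = np.zeros((1, 32, 32))
        scene = ImageScene(data, ["CD20"], 0.05)
        scene.data = scene.data.astype(float)
        scene.data[0, 0, 0] = np.inf  # bypass constructor check on purpose
        with pytest.raises(ValueError, match="non-finite"):
            detect_clusters(scene, "CD20")

    def test_watershed_splits_two_maxima_blob(self):
        # two Gaussians close enough to merge above threshold but with
        # two distinct intensity maxima; oracle = maxima count
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.zeros((64, 64))
        for cx in (28, 38):
            img += 1000 * np.exp(-((yy - 32) ** 2 + (xx - cx) ** 2) / (2 * 4.0**2))
        n_maxima = len(peak_local_max(img, min_distance=3))
        assert n_maxima == 2
        blob_above_otsu = ndimage.label(img > img.max() / 2)[1]
        assert blob_above_otsu == 1  # genuinely merged
        scene = ImageScene(img[np.newaxis], ["CD20"], 0.05)
        _, table = detect_clusters(
            scene, "CD20", ClusterParams(maxima_min_distance_px=3,
                                         smooth_sigma_px=0.0)
        )
        assert len(table) == n_maxima

    def test_offset_invariance_under_constant_shift(self):
        scene, _ = synthetic.simulate_cluster_image(10, noise_sd=2.0, seed=4)
        params = ClusterParams(otsu_offset_percent=20.0)
        _, base = detect_clusters(scene, "CD20", params)
        shifted = ImageScene(
            scene.data + 57.0, scene.channel_names, scene.pixel_size_um
        )
        _, shift = detect_clusters(shifted, "CD20", params)
        assert len(shift) == len(base)
        assert shift["area_um2"].sum() == pytest.approx(
            base["area_um2"].sum(), rel=1e-9
        )

    def test_deterministic_labels(self):
        scene, _ = synthetic.simulate_cluster_image(8, noise_sd=1.0, seed=6)
        m1, _ = detect_clusters(scene, "CD20")
        m2, _ = detect_clusters(scene, "CD20")
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_area_identity(self):
        scene, _ = synthetic.simulate_cluster_image(5, noise_sd=0, seed=2)
        mask, table = detect_clusters(scene, "CD20", NOISELESS)
        for _, row in table.iterrows():
            n_px = int((mask.labels == row["cluster_id"]).sum())
            assert row["area_um2"] == pytest.approx(
                n_px * scene.pixel_area_um2
            )
            assert row["integrated_intensity"] == pytest.approx(
                row["mean_intensity"] * n_px
            )


class TestCountPlaSpots:
    def test_conservation(self):
        scene, truth = synthetic.simulate_pla_image(12, cell_count=3, seed=7)
        table, _ = count_pla_spots(scene)
        assert table["dots_per_cell"].sum() == 12

    def test_per_cell_counts_match_truth(self):
        scene, truth = synthetic.simulate_pla_image(15, cell_count=4, seed=8)
        table, _ = count_pla_spots(scene)
        assert sorted(table["dots_per_cell"]) == sorted(
            truth.derived["counts_per_cell"]
        )

    def test_min_area_filter_excludes_small_spot(self):
        scene, _ = synthetic.simulate_pla_image(6, cell_count=2, seed=9)
        table_all, mask = count_pla_spots(scene, min_spot_area_px=1)
        smallest = min(
            (mask.labels == rid).sum() for rid in mask.region_ids
        )
        table_filtered, _ = count_pla_spots(
            scene, min_spot_area_px=int(smallest) + 1
        )
        assert (
            table_filtered["dots_per_cell"].sum()
            < table_all["dots_per_cell"].sum()
        )

    def test_watershed_recovers_two_touching_spots(self):
        # two Gaussian dots 2.5 sigma apart: merged in the binary raster
        # but carrying two intensity maxima (the oracle)
        sigma = 3.0
        yy, xx = np.mgrid[0:48, 0:48]
        pla = np.zeros((48, 48))
        for cx in (20, 20 + 2.5 * sigma):
            pla += 800 * np.exp(
                -((yy - 24) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
            )
        assert len(peak_local_max(pla, min_distance=2)) == 2
        assert ndimage.label(pla > pla.max() / 2)[1] == 1
        dapi = np.zeros((48, 48))
        dapi[_disc(48, (24, 24), 20)] = 300.0
        scene = ImageScene(np.stack([dapi, pla]), ["DAPI", "PLA"], 0.1)
        table, mask = count_pla_spots(scene, smooth_sigma_px=0.0)
        assert table["dots_per_cell"].sum() == 2

    def test_no_cells_empty_table(self):
        scene = ImageScene(np.zeros((2, 32, 32)), ["DAPI", "PLA"], 0.1)
        table, _ = count_pla_spots(scene)
        assert table.empty


def _disc(size, center, radius):
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestCalibration:
    def test_noiseless_slope_one_exact_recovery(self):
        beads, _ = synthetic.simulate_calibration_beads(gain=0.02, noise_cv=0)
        curve = fit_calibration(beads)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        result = calibrate_molecules(beads, [0.02 * 95_000.0])
        assert result["molecules"].iloc[0] == pytest.approx(95_000.0, rel=1e-9)

    def test_sample_at_bead_mfi_recovers_bead_abc(self):
        beads, _ = synthetic.simulate_calibration_beads(gain=0.05, noise_cv=0)
        bead = beads[beads["kind"] == "bead"].iloc[2]
        result = calibrate_molecules(beads, [bead["mfi"]])
        assert result["molecules"].iloc[0] == pytest.approx(
            bead["abc"], rel=1e-9
        )

    def test_noisy_recovery_within_ten_percent(self):
        true_abc = 95_000.0
        recovered = []
        for seed in range(10):
            beads, _ = synthetic.simulate_calibration_beads(
                gain=0.02, noise_cv=0.05, sample_abcs=[true_abc], seed=seed
            )
            sample_mfi = beads.loc[beads["kind"] == "sample", "mfi"].iloc[0]
            result = calibrate_molecules(
                beads[beads["kind"] == "bead"], [sample_mfi]
            )
            recovered.append(result["molecules"].iloc[0])
        assert np.mean(recovered) == pytest.approx(true_abc, rel=0.10)

    def test_fewer_than_three_beads_rejected(self):
        beads = pd.DataFrame(
            {"kind": ["bead"] * 2, "abc": [1e3, 1e4], "mfi": [20.0, 200.0]}
        )
        with pytest.raises(ValueError, match="3 bead"):
            fit_calibration(beads)

    def test_nonpositive_sample_rejected(self):
        beads, _ = synthetic.simulate_calibration_beads(noise_cv=0)
        with pytest.raises(ValueError, match="positive"):
            calibrate_molecules(beads, [0.0])

    def test_out_of_range_flagged(self):
        beads, _ = synthetic.simulate_calibration_beads(gain=0.02, noise_cv=0)
        huge = beads["mfi"].max() * 100
        result = calibrate_molecules(beads, [huge])
        assert not result["in_range"].iloc[0]


class TestMoleculesPerCluster:
    def _table(self, intensities):
        return pd.DataFrame(
            {
                "cluster_id": range(1, len(intensities) + 1),
                "integrated_intensity": intensities,
            }
        )

    def test_single_cluster_gets_all(self):
        out = molecules_per_cluster(self._table([123.0]), 90_000.0)
        assert out["molecules"].iloc[0] == 90_000.0

    def test_equal_split(self):
        out = molecules_per_cluster(self._table([50.0, 50.0]), 10_000.0)
        np.testing.assert_allclose(out["molecules"], [5000.0, 5000.0])

    @given(
        st.lists(st.floats(0.1, 1e6), min_size=1, max_size=20),
        st.floats(1.0, 1e7),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, intensities, total):
        out = molecules_per_cluster(self._table(intensities), total)
        assert out["molecules"].sum() == pytest.approx(total, rel=1e-9)
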