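import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import spatialtme as st
from spatialtme.detection import MarkerThresholds
from spatialtme.synthetic import assign_markers, render_scene


def single_cell_scene(panel, level="+", marker="CD4", pos=(60.0, 40.0)):
    cells = assign_markers(np.array([list(pos)]), panel, {marker: 1.0}, seed=0)
    cells.at[0, "levels"] = {marker: level}
    return cells, render_scene(cells, panel, image_shape=(100, 120))


class TestChannels:
    def test_split_is_lossless(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (20, 30, 3)).astype(np.uint8)
        r, g, b = st.split_channels(img)
        np.testing.assert_array_equal(np.stack([r, g, b], axis=-1), img)

    def test_pure_red_image(self):
        img = np.zeros((10, 10, 3), np.uint8)
        img[:, :, 0] = 77
        r, g, b = st.split_channels(img)
        assert (r == 77).all() and g.sum() == 0 and b.sum() == 0

    def test_wrong_channel_count_is_a_format_error(self):
        with pytest.raises(ValueError):
            st.split_channels(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            st.split_channels(np.zeros((10, 10, 4)))


class TestMarkerMask:
    def test_all_zero_channel_gives_empty_mask(self):
        thr = MarkerThresholds({"CD4": 60.0})
        mask = st.extract_marker_mask(np.zeros((50, 50)), "CD4", thr)
        assert not mask.any()

    def test_small_objects_are_denoised_away(self):
        channel = np.zeros((60, 60))
        channel[10:20, 10:15] = 100.0  # 50 px blob
        channel[40, 40] = channel[40, 41] = 100.0  # three 2-px specks
        channel[50, 10] = channel[50, 11] = 100.0
        channel[5, 50] = channel[6, 50] = 100.0
        thr = MarkerThresholds({"CD4": 60.0})
        mask = st.extract_marker_mask(channel, "CD4", thr, min_object_px=10)
        from scipy.ndimage import label

        _, n = label(mask)
        assert n == 1
        assert mask.sum() == 50

    def test_zero_min_object_px_equals_plain_thresholding(self):
        rng = np.random.default_rng(1)
        channel = rng.uniform(0, 255, (40, 40))
        thr = MarkerThresholds({"CD8": 60.0})
        mask = st.extract_marker_mask(channel, "CD8", thr, min_object_px=0)
        np.testing.assert_array_equal(mask, channel >= 60.0)

    def test_missing_threshold_is_a_configuration_error(self):
        with pytest.raises(KeyError):
            st.extract_marker_mask(np.zeros((5, 5)), "CD99", MarkerThresholds({"CD4": 1.0}))


class TestDetectNuclei:
    def test_blank_image_yields_zero_nuclei(self):
        cent, labels = st.detect_nuclei(np.zeros((64, 64)))
        assert len(cent) == 0 and labels.max() == 0

    def test_single_nucleus_centroid_within_two_pixels(self, panel1):
        _, scene = single_cell_scene(panel1)
        cent, labels = st.detect_nuclei(
            scene.nuclear_map, st.NucleusDetectorConfig(threshold=50.0)
        )
        assert len(cent) == 1
        assert np.hypot(cent[0, 0] - 60.0, cent[0, 1] - 40.0) < 2.0

    def test_two_nuclei_forty_pixels_apart_get_two_labels(self, panel1):
        cells = assign_markers(
            np.array([[30.0, 50.0], [70.0, 50.0]]), panel1, {"CD4": 1.0}, seed=0
        )
        scene = render_scene(cells, panel1, image_shape=(100, 100), nucleus_radius=6)
        cent, labels = st.detect_nuclei(
            scene.nuclear_map, st.NucleusDetectorConfig(threshold=50.0, min_distance=6)
        )
        assert len(cent) == 2
        assert labels.max() == 2


class TestTypeCells:
    def test_membership_and_bins(self, panel1):
        thr = MarkerThresholds.default(panel1.markers, 60.0)
        shape = (50, 50)
        masks = {m: np.zeros(shape, bool) for m in panel1.markers}
        maps = {m: np.zeros(shape) for m in panel1.markers}
        masks["CD4"][10, 10] = True
        maps["CD4"][10, 10] = 2.5 * 60.0  # value 2.5X -> '++'
        cells = st.type_cells(np.array([[10.0, 10.0]]), masks, maps, panel1, thr)
        assert cells["markers"].iloc[0] == frozenset({"CD4"})
        assert cells["levels"].iloc[0] == {"CD4": "++"}

    def test_multi_positive_cell(self, panel2):
        thr = MarkerThresholds.default(panel2.markers, 60.0)
        shape = (50, 50)
        masks = {m: np.zeros(shape, bool) for m in panel2.markers}
        maps = {m: np.full(shape, 70.0) for m in panel2.markers}
        masks["CD8"][:, :] = True
        masks["CD133"][:, :] = True
        cells = st.type_cells(np.array([[25.0, 25.0]]), masks, maps, panel2, thr)
        assert cells["markers"].iloc[0] == frozenset({"CD8", "CD133"})

    def test_centroid_outside_image_is_an_error(self, panel1):
        thr = MarkerThresholds.default(panel1.markers)
        masks = {"CD4": np.zeros((20, 20), bool)}
        maps = {"CD4": np.zeros((20, 20))}
        with pytest.raises(ValueError):
            st.type_cells(np.array([[100.0, 5.0]]), masks, maps, panel1, thr)

    def test_bin_is_monotone_in_intensity(self):
        thr = MarkerThresholds({"CD4": 60.0})
        order = {None: 0, "+": 1, "++": 2, "+++": 3}
        values = np.linspace(0, 300, 61)
        bins = [order[thr.bin("CD4", v)] for v in values]
        assert bins == sorted(bins)
        assert thr.bin("CD4", 59.9) is None
        assert thr.bin("CD4", 60.0) == "+"
        assert thr.bin("CD4", 120.0) == "++"
        assert thr.bin("CD4", 180.0) == "+++"


class TestHScore:
    @pytest.mark.parametrize(
        "low,med,high,expected",
        [(0, 0, 100, 300), (0, 0, 0, 0), (50, 25, 25, 175), (100, 0, 0, 100)],
    )
    def test_forced_arithmetic(self, low, med, high, expected):
        assert st.compute_h_score(low, med, high) == expected

    @given(
        hst.lists(hst.floats(0, 1), min_size=3, max_size=3).filter(
            lambda v: sum(v) <= 1
        )
    )
    def test_equals_dot_product_oracle(self, fractions):
        pct = [100 * f for f in fractions]
        oracle = float(np.dot([1, 2, 3], pct))
        assert st.compute_h_score(*pct) == pytest.approx(oracle)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError):
            st.compute_h_score(60, 30, 30)


class TestRegionsAndQuantities:
    def _cells(self, xs, ys, markers):
        return pd.DataFrame(
            {
                "cell_id": range(len(xs)),
                "x": xs,
                "y": ys,
                "panel": 1,
                "markers": markers,
                "levels": [
                    {m: "+" for m in mk} for mk in markers
                ],
            }
        )

    def test_region_assignment_is_a_partition(self):
        rng = np.random.default_rng(2)
        n = 200
        cells = self._cells(
            rng.uniform(0, 99, n), rng.uniform(0, 99, n),
            [frozenset({"CD4"})] * n,
        )
        tn = np.zeros((100, 100), bool)
        ts = np.zeros((100, 100), bool)
        tn[:, :40] = True
        ts[:, 60:] = True
        out = st.assign_region(cells, tn, ts)
        counts = out["region"].value_counts()
        assert counts.sum() == n
        assert set(out["region"]) <= {"TN", "TS", "none"}
        assert (out.loc[out["x"] < 39, "region"] == "TN").all()

    def test_overlapping_masks_rejected(self):
        cells = self._cells([5.0], [5.0], [frozenset({"CD4"})])
        m = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            st.assign_region(cells, m, m)

    def test_density_for_one_square_millimetre(self):
        # 2000 x 2000 px at 0.5 um/px = 1 mm^2
        rng = np.random.default_rng(3)
        cells = self._cells(
            rng.uniform(0, 1999, 100), rng.uniform(0, 1999, 100),
            [frozenset({"CD4"})] * 100,
        )
        cells["region"] = "TN"
        q = st.summarize_quantities(cells, {"TN": 2000 * 2000}, microns_per_pixel=0.5)
        row = q[(q["phenotype"] == "CD4") & (q["region"] == "TN")].iloc[0]
        assert row["density_per_mm2"] == pytest.approx(100.0)
        assert row["percentage"] == pytest.approx(100.0)

    def test_density_round_trip_at_2000_per_mm2(self, panel1):
        # construct at 2000 cells/mm^2 and measure the same density back
        from spatialtme.synthetic import ProcessSpec, assign_markers, simulate_point_pattern

        mpp = 0.5
        shape = (1000, 1000)  # 0.25 mm^2
        area_mm2 = shape[0] * shape[1] * mpp**2 * 1e-6
        mask = np.ones(shape, bool)
        pts = simulate_point_pattern(
            mask, ProcessSpec("poisson", 2000 * area_mm2 / mask.sum()), seed=8
        )
        cells = assign_markers(pts, panel1, {"CD4": 1.0}, seed=9)
        cells["region"] = "TN"
        q = st.summarize_quantities(cells, {"TN": mask.sum()}, microns_per_pixel=mpp)
        row = q[(q["phenotype"] == "CD4") & (q["region"] == "TN")].iloc[0]
        se = np.sqrt(2000 / area_mm2)  # Poisson SE on the density scale
        assert abs(row["density_per_mm2"] - 2000) < 3 * se

    def test_single_positive_percentages_partition_to_100(self):
        rng = np.random.default_rng(4)
        n = 120
        markers = [frozenset({rng.choice(["CD4", "CD20", "CD38"])}) for _ in range(n)]
        cells = self._cells(rng.uniform(0, 50, n), rng.uniform(0, 50, n), markers)
        cells["region"] = "TS"
        q = st.summarize_quantities(cells, {"TS": 2500}, microns_per_pixel=0.5)
        assert q["percentage"].sum() == pytest.approx(100.0)

    def test_zero_area_region_flags_missing_density(self):
        cells = self._cells([1.0], [1.0], [frozenset({"CD4"})])
        cells["region"] = "TN"
        q = st.summarize_quantities(cells, {"TN": 1, "TS": 0}, microns_per_pixel=0.5)
        ts = q[q["region"] == "TS"].iloc[0]
        assert np.isnan(ts["density_per_mm2"])

    def test_round_trip_marker_sets_match_ground_truth(self, separated_scene, panel1):
        scene = separated_scene
        cent, _ = st.detect_nuclei(
            scene.nuclear_map, st.NucleusDetectorConfig(threshold=50.0, min_distance=6)
        )
        thr = scene.thresholds
        masks = {
            m: st.extract_marker_mask(scene.marker_maps[m], m, thr)
            for m in panel1.markers
        }
        typed = st.type_cells(cent, masks, scene.marker_maps, panel1, thr)
        gt = scene.ground_truth.cells
        from scipy.spatial import cKDTree

        d, idx = cKDTree(gt[["x", "y"]].to_numpy()).query(typed[["x", "y"]].to_numpy())
        assert d.max() < 3.0
        assert len(typed) == len(gt)
        for k in range(len(typed)):
            assert typed["markers"].iloc[k] == gt["markers"].iloc[idx[k]]
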