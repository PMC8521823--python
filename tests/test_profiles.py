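"""Quantification: per-object intensity, positivity calls, depth profiles."""

import numpy as np
import pandas as pd
import pytest

from spheroquant import (
    ChannelImage,
    LabelMap,
    classify_positive,
    infiltration_count_profile,
    mean_intensity_profile,
    measure_object_intensity,
    positive_fraction_profile,
    ratio_profile,
)
from spheroquant.errors import (
    DegenerateDistributionError,
    ParameterError,
    ShapeError,
)
from spheroquant.profiles import DepthProfile, annulus_areas_um2
from spheroquant.segmentation import ACCEPTED


def _records(depths, inside=None, **extra_cols):
    depths = np.asarray(depths, dtype=float)
    if inside is None:
        inside = depths >= 0
    df = pd.DataFrame(
        {
            "object_id": np.arange(1, len(depths) + 1),
            "distance_to_surface_um": depths,
            "inside_spheroid": inside,
        }
    )
    for name, values in extra_cols.items():
        df[name] = values
    return df


class TestMeasureObjectIntensity:
    def _label_map(self, labels):
        ids = [int(k) for k in np.unique(labels) if k]
        return LabelMap(labels, {k: ACCEPTED for k in ids}, 1.0)

    def test_constant_field(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:6, 2:6] = 1  # area 16
        img = ChannelImage("c", np.full((10, 10), 7.0), 1.0)
        out = measure_object_intensity(self._label_map(labels), img)
        row = out.iloc[0]
        assert row["mean"] == 7.0
        assert row["median"] == 7.0
        assert row["integrated"] == 7.0 * 16

    def test_singleton_pixel(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 2] = 1
        img_pixels = np.zeros((5, 5))
        img_pixels[2, 2] = 7.0
        out = measure_object_intensity(
            self._label_map(labels), ChannelImage("c", img_pixels, 1.0)
        )
        assert (out[["mean", "median", "integrated"]].iloc[0] == 7.0).all()

    def test_half_and_half_matches_direct_summation(self):
        """Oracle: direct summation over the listed member pixels."""
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1:3, 1:5] = 1  # 8 pixels
        pixels = np.zeros((8, 8))
        pixels[1, 1:5] = 3.0
        pixels[2, 1:5] = 11.0
        img = ChannelImage("c", pixels, 1.0)
        out = measure_object_intensity(self._label_map(labels), img)
        member = pixels[labels == 1]
        assert out["mean"].iloc[0] == pytest.approx(member.mean())
        assert out["integrated"].iloc[0] == pytest.approx(member.sum())
        assert out["mean"].iloc[0] == pytest.approx((3 + 11) / 2)

    def test_shape_mismatch(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        with pytest.raises(ShapeError):
            measure_object_intensity(
                self._label_map(labels), ChannelImage("c", np.ones((5, 4)), 1.0)
            )


class TestClassifyPositive:
    def test_manual_threshold(self):
        flags, thr = classify_positive(
            np.array([5.0, 15.0]), "manual", manual_threshold=10.0
        )
        assert list(flags) == [False, True]
        assert thr == 10.0

    def test_all_equal_means_manual_above(self):
        flags, _ = classify_positive(
            np.full(5, 3.0), "manual", manual_threshold=4.0
        )
        assert not flags.any()

    def test_automatic_needs_two_distinct_values(self):
        with pytest.raises(DegenerateDistributionError):
            classify_positive(np.full(4, 2.0), "automatic")

    def test_automatic_recovers_phantom_death_calls(self, small_phantom):
        """Otsu on per-nucleus DRAQ7 means (positives ~5x brighter) agrees
        with ground truth for >= 95% of matched nuclei."""
        from scipy.spatial import cKDTree

        from spheroquant import PrimaryParams, identify_primary_objects, merge_channels

        params, image, truth = small_phantom
        nuclear = merge_channels(
            [image["mAG"], image["mKO2"], image["DRAQ7"]]
        )
        nuclei = identify_primary_objects(nuclear, PrimaryParams(5, 20))
        feats = measure_object_intensity(nuclei, image["DRAQ7"])
        flags, _ = classify_positive(feats["mean"].to_numpy(), "automatic")
        centroids = []
        for k in sorted(nuclei.accepted_labels):
            rr, cc = np.nonzero(nuclei.labels == k)
            centroids.append((rr.mean(), cc.mean()))
        gt = truth.nuclei[["row", "col"]].to_numpy()
        dist, idx = cKDTree(gt).query(np.asarray(centroids), k=1)
        matched = dist <= truth.nuclei["radius_px"].to_numpy()[idx]
        agree = (
            flags[matched]
            == truth.nuclei["draq7_positive"].to_numpy()[idx[matched]]
        )
        assert agree.mean() >= 0.95


class TestMeanIntensityProfile:
    def test_single_bin_mean(self):
        rec = _records([10.0, 20.0], pimonidazole_mean=[2.0, 4.0])
        prof = mean_intensity_profile(rec, "pimonidazole", 25.0)
        assert prof.value[0] == 3.0
        assert prof.n_objects[0] == 2

    def test_empty_records_all_undefined(self):
        rec = _records([], pimonidazole_mean=[])
        prof = mean_intensity_profile(rec, "pimonidazole", 25.0)
        assert prof.n_objects.sum() == 0
        assert np.isnan(prof.value).all()

    def test_missing_channel_column(self):
        rec = _records([10.0])
        with pytest.raises(ParameterError):
            mean_intensity_profile(rec, "pimonidazole", 25.0)

    def test_refining_bins_reaggregates_exactly(self):
        """Halving the bin width and re-averaging with n-weights reproduces
        the coarse profile bin for bin."""
        rng = np.random.default_rng(8)
        depths = rng.uniform(0, 200, 400)
        rec = _records(depths, pimonidazole_mean=rng.random(400) * 50)
        coarse = mean_intensity_profile(rec, "pimonidazole", 50.0)
        fine = mean_intensity_profile(
            rec, "pimonidazole", 25.0, max_depth_um=coarse.bin_edges_um[-1]
        )
        for i in range(coarse.n_bins):
            n = fine.n_objects[2 * i : 2 * i + 2]
            v = fine.value[2 * i : 2 * i + 2]
            if n.sum() == 0:
                assert np.isnan(coarse.value[i])
                continue
            weighted = np.nansum(v * n) / n.sum()
            assert coarse.value[i] == pytest.approx(weighted, rel=1e-12)

    def test_conservation(self):
        rng = np.random.default_rng(9)
        depths = np.concatenate([rng.uniform(0, 120, 50), [-5.0, -1.0]])
        rec = _records(depths, pimonidazole_mean=np.ones(52))
        prof = mean_intensity_profile(rec, "pimonidazole", 30.0)
        assert prof.n_objects.sum() == 50


class TestPositiveFractionProfile:
    def test_all_positive_is_one(self):
        rec = _records([5, 30, 55.0], DRAQ7_positive=[True] * 3)
        prof = positive_fraction_profile(rec, "DRAQ7", 25.0)
        defined = prof.value[prof.defined]
        np.testing.assert_allclose(defined, 1.0)

    def test_empty_bin_undefined_with_zero_count(self):
        rec = _records([10.0, 60.0], DRAQ7_positive=[True, False])
        prof = positive_fraction_profile(rec, "DRAQ7", 25.0)
        assert prof.n_objects[1] == 0
        assert 1 in prof.undefined_bins

    def test_invariant_under_relabelling(self):
        rng = np.random.default_rng(5)
        depths = rng.uniform(0, 100, 60)
        flags = rng.random(60) < 0.4
        rec = _records(depths, DRAQ7_positive=flags)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["object_id"] = np.arange(1, 61)
        a = positive_fraction_profile(rec, "DRAQ7", 20.0)
        b = positive_fraction_profile(shuffled, "DRAQ7", 20.0)
        np.testing.assert_array_equal(a.n_objects, b.n_objects)
        np.testing.assert_allclose(a.value, b.value, equal_nan=True)

    def test_fraction_bounds(self):
        rng = np.random.default_rng(6)
        rec = _records(
            rng.uniform(0, 150, 100), DRAQ7_positive=rng.random(100) < 0.5
        )
        prof = positive_fraction_profile(rec, "DRAQ7", 25.0)
        defined = prof.value[prof.defined]
        assert ((defined >= 0) & (defined <= 1)).all()


class TestInfiltrationProfile:
    def test_no_pbmcs_zero_profile(self):
        rec = _records([])
        prof = infiltration_count_profile(rec, 25.0)
        assert prof.value.sum() == 0
        assert prof.extra["outside_count"] == 0

    def test_counts_plus_outside_conserved(self):
        depths = [10.0, 30.0, -4.0, 80.0, -0.5]
        rec = _records(depths)
        prof = infiltration_count_profile(rec, 25.0)
        assert prof.n_objects.sum() + prof.extra["outside_count"] == len(depths)
        assert prof.extra["outside_count"] == 2

    def test_ring_area_normalization(self):
        rec = _records([10.0, 12.0, 40.0])
        prof = infiltration_count_profile(
            rec, 25.0, normalize="ring_area", spheroid_radius_um=100.0
        )
        areas = annulus_areas_um2(prof.bin_edges_um, 100.0)
        np.testing.assert_allclose(
            prof.value, prof.n_objects / areas
        )
        # annulus areas tile the disk
        full = annulus_areas_um2(np.arange(0, 101, 25.0), 100.0)
        assert full.sum() == pytest.approx(np.pi * 100.0**2)

    def test_ring_area_requires_radius(self):
        with pytest.raises(ParameterError):
            infiltration_count_profile(
                _records([10.0]), 25.0, normalize="ring_area"
            )


class TestRatioProfile:
    def test_equal_counts_ratio_one(self):
        rec = _records(
            [10, 12, 14, 16.0],
            mKO2_positive=[True, True, False, False],
            mAG_positive=[False, False, True, True],
        )
        prof = ratio_profile(rec, bin_width_um=25.0)
        assert prof.value[0] == 1.0
        assert prof.extra["numerator_counts"][0] == 2
        assert prof.extra["denominator_counts"][0] == 2

    def test_zero_denominator_is_undefined_not_infinite(self):
        rec = _records(
            [10.0, 12.0],
            mKO2_positive=[True, True],
            mAG_positive=[False, False],
        )
        prof = ratio_profile(rec, bin_width_um=25.0)
        assert np.isnan(prof.value[0])
        assert 0 in prof.undefined_bins

    def test_missing_flags_rejected(self):
        with pytest.raises(ParameterError):
            ratio_profile(_records([10.0]), bin_width_um=25.0)


class TestDepthProfileContract:
    def test_bin_edges_must_start_at_zero(self):
        with pytest.raises(ParameterError):
            DepthProfile(
                np.array([10.0, 20.0]), np.array([1]), np.array([1.0]), "count"
            )

    def test_to_frame_round_trip_columns(self):
        prof = DepthProfile(
            np.array([0.0, 25.0, 50.0]),
            np.array([3, 0]),
            np.array([1.5, np.nan]),
            "mean_intensity",
        )
        df = prof.to_frame()
        assert list(df["defined"]) == [True, False]
        assert list(df["n_objects"]) == [3, 0]
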