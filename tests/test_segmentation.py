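"""Segmentation: primary objects with declumping, secondary propagation,
spheroid detection, and the LabelMap contract."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from spheroquant import (
    ChannelImage,
    LabelMap,
    PrimaryParams,
    SecondaryParams,
    identify_primary_objects,
    identify_secondary_objects,
    identify_spheroid,
)
from spheroquant.errors import (
    InputError,
    NoSpheroidFoundError,
    ParameterError,
    ShapeError,
)
from spheroquant.segmentation import (
    ACCEPTED,
    DISCARDED_BORDER,
    DISCARDED_SIZE,
)
from tests.conftest import rasterized_disk


def _disk_image(centers, radius=10.0, size=96, value=100.0, pixel_size=1.0):
    img = np.zeros((size, size))
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    for r0, c0 in centers:
        img[np.hypot(rr - r0, cc - c0) <= radius] = value
    return ChannelImage("DAPI", img, pixel_size)


class TestLabelMapContract:
    def test_labels_must_be_consecutive(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1, 1] = 2  # gap: no label 1
        with pytest.raises(ValueError):
            LabelMap(labels, {2: ACCEPTED}, 1.0)

    def test_every_label_needs_a_category(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1, 1] = 1
        with pytest.raises(ValueError):
            LabelMap(labels, {}, 1.0)

    def test_accepted_only_relabels_consecutively(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[0, 0] = 1
        labels[3, 3] = 2
        labels[6, 6] = 3
        lm = LabelMap(
            labels, {1: DISCARDED_BORDER, 2: ACCEPTED, 3: ACCEPTED}, 1.0
        )
        acc = lm.accepted_only()
        assert acc.n_objects == 2
        assert sorted(np.unique(acc.labels)) == [0, 1, 2]
        assert acc.labels[3, 3] == 1 and acc.labels[6, 6] == 2


class TestIdentifyPrimary:
    def test_all_zero_image_gives_no_objects(self):
        img = ChannelImage("DAPI", np.zeros((64, 64)), 1.0)
        lm = identify_primary_objects(img, PrimaryParams(5, 30))
        assert lm.n_objects == 0

    def test_two_separated_disks_recovered_with_subpixel_centroids(self):
        centers = [(30.0, 30.0), (70.0, 66.0)]
        img = _disk_image(centers, radius=10, size=104)
        lm = identify_primary_objects(
            img, PrimaryParams(15, 25, maxima_min_distance_px=8)
        )
        assert len(lm.accepted_labels) == 2
        for k in lm.accepted_labels:
            rr, cc = np.nonzero(lm.labels == k)
            centroid = np.array([rr.mean(), cc.mean()])
            err = min(
                np.hypot(*(centroid - np.array(c))) for c in centers
            )
            assert err <= 1.0

    def test_border_touching_disk_discarded_border(self):
        img = _disk_image([(5.0, 40.0)], radius=10, size=80)
        lm = identify_primary_objects(
            img, PrimaryParams(15, 25, exclude_border=True)
        )
        assert lm.n_objects == 1
        assert lm.categories[1] == DISCARDED_BORDER
        # same image with exclusion off: accepted or size-gated, not border
        lm2 = identify_primary_objects(
            img, PrimaryParams(15, 25, exclude_border=False)
        )
        assert DISCARDED_BORDER not in lm2.categories.values()

    def test_border_gate_overrides_size_gate(self):
        """A border-touching object out of size range is still yellow."""
        img = _disk_image([(3.0, 40.0)], radius=4, size=80)
        lm = identify_primary_objects(img, PrimaryParams(15, 25))
        assert set(lm.categories.values()) == {DISCARDED_BORDER}

    def test_size_gate_classifies_by_equivalent_diameter(self):
        img = _disk_image([(25.0, 25.0)], radius=5, size=96)
        img.pixels[60:80, 60:84] = 100.0  # a big rectangle, eq diam ~24.7
        lm = identify_primary_objects(
            img, PrimaryParams(8, 16, maxima_min_distance_px=12)
        )
        cats = lm.categories
        areas = {
            k: np.sum(lm.labels == k) for k in cats
        }
        for k, cat in cats.items():
            d = np.sqrt(4 * areas[k] / np.pi)
            if cat == ACCEPTED:
                assert 8 <= d <= 16
            elif cat == DISCARDED_SIZE:
                assert d < 8 or d > 16

    def test_fused_disks_split_or_merge_with_maxima_distance(self, two_disk_image):
        img, centers = two_disk_image
        small = identify_primary_objects(
            img, PrimaryParams(10, 30, maxima_min_distance_px=7,
                               exclude_border=False)
        )
        assert len(small.accepted_labels) == 2
        large = identify_primary_objects(
            img, PrimaryParams(10, 30, maxima_min_distance_px=30,
                               exclude_border=False)
        )
        assert len(large.accepted_labels) == 1

    def test_split_count_monotone_in_maxima_distance(self, two_disk_image):
        img, _ = two_disk_image
        counts = []
        for md in (3, 5, 7, 10, 14, 20, 30):
            lm = identify_primary_objects(
                img, PrimaryParams(3, 40, maxima_min_distance_px=md,
                                   exclude_border=False)
            )
            counts.append(lm.n_objects)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_manual_without_threshold_rejected(self):
        img = ChannelImage("DAPI", np.ones((16, 16)), 1.0)
        with pytest.raises(ParameterError):
            identify_primary_objects(
                img, PrimaryParams(5, 20, threshold_strategy="manual")
            )

    def test_phantom_recovery_f1(self, clean_phantom):
        """On well-separated bright nuclei, detection matches ground truth."""
        params, image, truth = clean_phantom
        lm = identify_primary_objects(
            image["DAPI"], PrimaryParams(5, 20)
        )
        got = []
        for k in lm.accepted_labels:
            rr, cc = np.nonzero(lm.labels == k)
            got.append((rr.mean(), cc.mean()))
        got = np.array(got)
        gt = truth.nuclei[["row", "col"]].to_numpy()
        dist, idx = cKDTree(got).query(gt, k=1)
        radius_px = truth.nuclei["radius_px"].to_numpy()
        matched = dist <= radius_px
        # one-to-one: a detection may match at most one truth nucleus
        tp = len(set(idx[matched]))
        precision = tp / len(got)
        recall = tp / len(gt)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95


class TestIdentifySecondary:
    def _seeds(self, size=96):
        labels = np.zeros((size, size), dtype=np.int32)
        labels[30:36, 30:36] = 1
        labels[30:36, 60:66] = 2
        labels[70:76, 45:51] = 3
        return LabelMap(labels, {k: ACCEPTED for k in (1, 2, 3)}, 1.0)

    def _bruteforce_assignment(self, seeds: LabelMap, cap: float):
        """Oracle: per-pixel nearest seed via KDTree per seed pixel set,
        lower label winning ties."""
        lab = seeds.labels
        h, w = lab.shape
        pts = np.column_stack(
            [g.ravel() for g in np.meshgrid(
                np.arange(h), np.arange(w), indexing="ij")]
        ).astype(float)
        best = np.full(h * w, np.inf)
        winner = np.zeros(h * w, dtype=int)
        for k in sorted(seeds.accepted_labels):
            coords = np.column_stack(np.nonzero(lab == k)).astype(float)
            d = cKDTree(coords).query(pts, k=1)[0]
            closer = d < best
            best[closer] = d[closer]
            winner[closer] = k
        winner[best > cap] = 0
        return winner.reshape(h, w)

    def test_zero_expansion_is_identity(self):
        seeds = self._seeds()
        guide = ChannelImage("pimo", np.zeros((96, 96)), 1.0)
        out = identify_secondary_objects(
            seeds, guide, SecondaryParams(max_expansion_px=0)
        )
        np.testing.assert_array_equal(out.labels, seeds.labels)

    @pytest.mark.parametrize("cap", [3.0, 5.0, 12.0])
    def test_matches_bruteforce_nearest_seed(self, cap):
        seeds = self._seeds()
        guide = ChannelImage("pimo", np.zeros((96, 96)), 1.0)
        out = identify_secondary_objects(
            seeds, guide, SecondaryParams(max_expansion_px=cap)
        )
        np.testing.assert_array_equal(
            out.labels, self._bruteforce_assignment(seeds, cap)
        )

    def test_superset_and_cap_invariants(self):
        seeds = self._seeds()
        guide = ChannelImage("pimo", np.full((96, 96), 50.0), 1.0)
        cap = 8.0
        out = identify_secondary_objects(
            seeds, guide, SecondaryParams(max_expansion_px=cap)
        )
        # superset of seed, same label
        sl = seeds.labels
        assert np.all(out.labels[sl > 0] == sl[sl > 0])
        # distance cap (centre-to-centre to the seed's pixel set)
        for k in out.accepted_labels:
            mine = np.column_stack(np.nonzero(out.labels == k)).astype(float)
            seed_pts = np.column_stack(np.nonzero(sl == k)).astype(float)
            d = cKDTree(seed_pts).query(mine, k=1)[0]
            assert d.max() <= cap + 1e-9

    def test_equidistant_frontier_ties_to_lower_label(self):
        """Two single-pixel seeds: the midline column is equidistant and
        must go to the lower label."""
        labels = np.zeros((11, 21), dtype=np.int32)
        labels[5, 4] = 1
        labels[5, 16] = 2
        seeds = LabelMap(labels, {1: ACCEPTED, 2: ACCEPTED}, 1.0)
        guide = ChannelImage("pimo", np.zeros((11, 21)), 1.0)
        out = identify_secondary_objects(
            seeds, guide, SecondaryParams(max_expansion_px=7.0)
        )
        mid = out.labels[:, 10]
        assert set(mid[mid > 0]) == {1}
        # and no assigned pixel is strictly closer to the other seed
        for k, other in ((1, (5, 16)), (2, (5, 4))):
            rr, cc = np.nonzero(out.labels == k)
            own = (5, 4) if k == 1 else (5, 16)
            d_own = np.hypot(rr - own[0], cc - own[1])
            d_other = np.hypot(rr - other[0], cc - other[1])
            assert np.all(d_own <= d_other + 1e-9)

    def test_only_accepted_seeds_propagate(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10:14, 10:14] = 1
        labels[25:29, 25:29] = 2
        seeds = LabelMap(labels, {1: ACCEPTED, 2: DISCARDED_SIZE}, 1.0)
        guide = ChannelImage("pimo", np.zeros((40, 40)), 1.0)
        out = identify_secondary_objects(
            seeds, guide, SecondaryParams(max_expansion_px=4)
        )
        assert out.n_objects == 1
        assert np.all(out.labels[labels == 2] == 0)

    def test_shape_mismatch(self):
        seeds = self._seeds()
        guide = ChannelImage("pimo", np.zeros((95, 96)), 1.0)
        with pytest.raises(ShapeError):
            identify_secondary_objects(seeds, guide, SecondaryParams())


class TestIdentifySpheroid:
    def test_disk_radius_100_equivalent_diameter_within_2pct(self):
        pixels, _, _ = rasterized_disk(100, pad=20)
        img = ChannelImage("DAPI", pixels, 1.0)
        mask = identify_spheroid(img, 200.0, "manual", 50.0)
        assert mask.equivalent_diameter_px == pytest.approx(200.0, rel=0.02)

    def test_all_zero_image_raises(self):
        img = ChannelImage("DAPI", np.zeros((128, 128)), 1.0)
        with pytest.raises(NoSpheroidFoundError):
            identify_spheroid(img, 60.0, "manual", 10.0)

    def test_dark_core_hole_filled(self):
        """A dim interior region (necrotic-core-like) must not punch a hole:
        the filled mask keeps >= 98% of the analytic disk area."""
        pixels, mask, center = rasterized_disk(80, pad=16)
        rr, cc = np.meshgrid(
            np.arange(pixels.shape[0]), np.arange(pixels.shape[1]),
            indexing="ij",
        )
        core = np.hypot(rr - center[0], cc - center[1]) <= 25
        pixels[core] = 0.0
        img = ChannelImage("DAPI", pixels, 1.0)
        sph = identify_spheroid(img, 160.0, "manual", 40.0)
        assert sph.mask.sum() >= 0.98 * np.pi * 80**2

    def test_automatic_threshold_fallback(self):
        pixels, _, _ = rasterized_disk(60, pad=12)
        img = ChannelImage("DAPI", pixels + 1.0, 1.0)
        sph = identify_spheroid(img, 120.0, "automatic")
        assert sph.equivalent_diameter_px == pytest.approx(120.0, rel=0.05)

    def test_perimeter_definition(self):
        """Perimeter = mask pixels with a background 4-neighbour (oracle:
        explicit scan)."""
        pixels, mask, _ = rasterized_disk(20, pad=5)
        sph = identify_spheroid(
            ChannelImage("DAPI", pixels, 1.0), 40.0, "manual", 50.0
        )
        m = sph.mask
        h, w = m.shape
        expected = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                if not m[r, c]:
                    continue
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr_, cc_ = r + dr, c + dc
                    if not (0 <= rr_ < h and 0 <= cc_ < w) or not m[rr_, cc_]:
                        expected[r, c] = True
        np.testing.assert_array_equal(sph.perimeter, expected)

    def test_non_finite_image_rejected_by_primary(self):
        bad = np.ones((16, 16))
        img = ChannelImage("DAPI", bad, 1.0)
        img.pixels = img.pixels.copy()
        img.pixels[0, 0] = np.inf  # bypass constructor check deliberately
        with pytest.raises(InputError):
            identify_primary_objects(img, PrimaryParams(5, 20))
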