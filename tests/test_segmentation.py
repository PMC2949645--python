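"""Segmentation chain: filters, IsoData threshold, watershed, particle filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk as disk_coords

from ihcquant import (
    ComponentImage,
    ImageScale,
    binarize_component,
    filter_nonround_particles,
    filter_small_particles,
    isodata_threshold,
    mean_filter,
    measure_particles,
    median_filter,
    segment_component,
    watershed_split,
)
from ihcquant.errors import DegenerateHistogramError, ValidationError

SCALE1 = ImageScale(1.0)


def isodata_fixed_points(hist):
    """Brute-force oracle: all t with round((mean<=t + mean>t)/2) == t."""
    hist = np.asarray(hist, dtype=float)
    values = np.arange(256)
    points = []
    for t in range(256):
        lo, hi = hist[: t + 1], hist[t + 1 :]
        m_lo = (values[: t + 1] * lo).sum() / lo.sum() if lo.sum() else t
        m_hi = (values[t + 1 :] * hi).sum() / hi.sum() if hi.sum() else t
        if int(round((m_lo + m_hi) / 2)) == t:
            points.append(t)
    return points


def spike_histogram(*pairs):
    hist = np.zeros(256, dtype=np.int64)
    for value, count in pairs:
        hist[value] = count
    return hist


class TestMeanFilter:
    def test_uniform_unchanged(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        np.testing.assert_array_equal(mean_filter(img, 3), img)

    def test_single_pixel_disk_average(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 255
        out = mean_filter(img, 1)  # radius-1 disk has 5 pixels
        assert out[4, 4] == 51  # round(255 / 5)

    def test_huge_radius_approaches_global_mean(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        out = mean_filter(img, 20)
        # replicate-edge padding biases corners; interior is near the mean
        assert abs(int(out[6, 6]) - img.mean()) <= 30


class TestIsoData:
    def test_two_spikes_midpoint(self):
        assert isodata_threshold(spike_histogram((50, 10), (200, 10))) == 125

    def test_uniform_histogram(self):
        assert isodata_threshold(np.ones(256)) in (127, 128)

    def test_adjacent_spikes(self):
        assert isodata_threshold(spike_histogram((10, 5), (11, 5))) == 10

    def test_degenerate_single_bin(self):
        with pytest.raises(DegenerateHistogramError):
            isodata_threshold(spike_histogram((42, 100)))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.dictionaries(
            st.integers(0, 255), st.integers(1, 10_000), min_size=2, max_size=40
        ).filter(lambda d: len(d) >= 2)
    )
    def test_threshold_is_always_an_intermeans_fixed_point(self, spikes):
        hist = spike_histogram(*spikes.items())
        assert isodata_threshold(hist) in isodata_fixed_points(hist)

    def test_matches_bruteforce_fixed_point_search(self, rng):
        for _ in range(200):
            n_bins = rng.integers(2, 30)
            bins = rng.choice(256, size=n_bins, replace=False)
            hist = spike_histogram(*((int(b), int(rng.integers(1, 1000))) for b in bins))
            t = isodata_threshold(hist)
            assert t in isodata_fixed_points(hist)


class TestBinarize:
    def test_blank_component_yields_empty_mask(self):
        comp = ComponentImage(np.full((8, 8), 255, dtype=np.uint8), "dab")
        assert not binarize_component(comp).any()

    def test_two_level_component_selects_dark_class(self):
        gray = np.full((10, 10), 220, dtype=np.uint8)
        gray[:3] = 60
        mask = binarize_component(ComponentImage(gray, "hematoxylin"))
        np.testing.assert_array_equal(mask > 0, gray == 60)

    def test_offset_shifts_threshold(self):
        gray = np.full((10, 10), 150, dtype=np.uint8)
        gray[:5] = 100
        comp = ComponentImage(gray, "dab")
        # isodata t = 125; offset -30 drops the 100 class too
        assert binarize_component(comp, 0).any()
        assert not binarize_component(comp, -30).any()

    def test_out_of_range_offset_rejected(self):
        comp = ComponentImage(np.zeros((4, 4), dtype=np.uint8), "dab")
        with pytest.raises(ValidationError):
            binarize_component(comp, -90)

    def test_noise_only_component_treated_as_unstained(self, rng):
        # unimodal near-white noise has no separable stained class
        gray = np.clip(rng.normal(252, 3, (64, 64)), 0, 255).round().astype(np.uint8)
        assert not binarize_component(ComponentImage(gray, "dab")).any()


class TestMedianFilter:
    def test_salt_noise_removed(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 255
        assert not median_filter(mask, 1).any()

    def test_empty_stays_empty_and_binary(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        out = median_filter(mask, 2)
        assert not out.any()
        assert set(np.unique(out)) <= {0}

    def test_solid_rectangle_mostly_preserved(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:16, 4:16] = 255
        out = median_filter(mask, 2)
        # corners may round; interior is untouched
        assert np.all(out[6:14, 6:14] == 255)
        assert abs(int((out > 0).sum()) - 144) <= 16


class TestWatershed:
    def test_single_disk_is_one_particle(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        rr, cc = disk_coords((20, 20), 10)
        mask[rr, cc] = 255
        assert watershed_split(mask, 2.2).max() == 1

    def test_two_overlapping_disks_split(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        for center in ((20, 20), (20, 34)):
            rr, cc = disk_coords(center, 10)
            mask[rr, cc] = 255
        assert watershed_split(mask, 2.2).max() == 2

    def test_empty_mask_gives_no_particles(self):
        assert watershed_split(np.zeros((10, 10), dtype=np.uint8)).max() == 0

    def test_splitting_only_adds_particles_and_removes_area(self, rng):
        from scipy import ndimage as ndi

        mask = (rng.random((64, 64)) < 0.4).astype(np.uint8) * 255
        mask = median_filter(mask, 1)
        labels = watershed_split(mask, 2.0)
        n_components = ndi.label(mask > 0, structure=np.ones((3, 3)))[0].max() if mask.any() else 0
        assert labels.max() >= n_components
        assert (labels > 0).sum() <= (mask > 0).sum()


class TestParticles:
    def test_square_area(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        (p,) = measure_particles(labels, SCALE1)
        assert p.area_px == 100
        assert p.area_um2 == pytest.approx(100.0)

    def test_disk_is_round_bar_is_not(self):
        labels = np.zeros((80, 80), dtype=np.int32)
        rr, cc = disk_coords((30, 30), 20)
        labels[rr, cc] = 1
        labels[70, 20:50] = 2  # 1 x 30 line
        disk_p, bar_p = measure_particles(labels, SCALE1)
        assert disk_p.circularity >= 0.9
        assert bar_p.circularity < 0.3

    def test_circularity_capped_at_one(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 2] = 1
        (p,) = measure_particles(labels, SCALE1)
        assert 0 < p.circularity <= 1.0


class TestParticleFilters:
    @staticmethod
    def _two_particles():
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[2:4, 2:4] = 1  # 4 px
        rr, cc = disk_coords((18, 18), 4)
        labels[rr, cc] = 2  # ~45 px
        return labels

    def test_small_particles_dropped_and_relabeled(self):
        out = filter_small_particles(self._two_particles(), 10.0, SCALE1)
        assert set(np.unique(out)) == {0, 1}
        assert (out == 1).sum() > 10

    def test_zero_threshold_is_identity(self):
        labels = self._two_particles()
        np.testing.assert_array_equal(filter_small_particles(labels, 0.0, SCALE1), labels)

    def test_roundness_filter_separates_disk_from_bar(self):
        labels = np.zeros((80, 80), dtype=np.int32)
        rr, cc = disk_coords((25, 25), 15)
        labels[rr, cc] = 1
        labels[70:73, 10:70] = 2  # 3 x 60 bar
        out = filter_nonround_particles(labels, 0.35)
        assert (out > 0).sum() == (labels == 1).sum()

    def test_zero_circularity_limit_is_identity(self):
        labels = self._two_particles()
        np.testing.assert_array_equal(filter_nonround_particles(labels, 0.0), labels)

    def test_filters_commute_on_h_component(self, default_scene, scene_config):
        from ihcquant import correct_blankfield, separate_stains

        image, blank, _ = default_scene
        h_comp, _ = separate_stains(correct_blankfield(image, blank))
        mask = median_filter(binarize_component(ComponentImage(mean_filter(h_comp.gray, 1), "hematoxylin")), 1)
        labels = watershed_split(mask, 4.4)
        scale = scene_config.scale
        a = filter_nonround_particles(filter_small_particles(labels, 10.0, scale), 0.35)
        b = filter_small_particles(filter_nonround_particles(labels, 0.35), 10.0, scale)
        np.testing.assert_array_equal(a > 0, b > 0)


def test_blank_component_segments_to_zero_particles():
    comp = ComponentImage(np.full((32, 32), 255, dtype=np.uint8), "dab")
    labels = segment_component(comp, ImageScale(2.2))
    assert labels.max() == 0
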