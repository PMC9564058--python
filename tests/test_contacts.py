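"""Local correlation maps, contact masks, event linking and classification."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mastreg.contacts import (
    ContactEvent,
    CorrelationParams,
    assign_contact_pairs,
    categorize_duration,
    classify_contacts,
    contact_mask,
    link_contact_events,
    local_correlation_map,
)
from mastreg.detect import Detection


def gaussian_weighted_pearson(red, green, sigma, eps=1e-12):
    """Independent brute-force oracle: per-pixel weighted Pearson coefficient."""
    r = int(3.0 * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    R = np.pad(red, r, mode="symmetric")
    G = np.pad(green, r, mode="symmetric")
    h, w = red.shape
    values = np.zeros((h, w))
    defined = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            wr = R[i:i + 2 * r + 1, j:j + 2 * r + 1]
            wg = G[i:i + 2 * r + 1, j:j + 2 * r + 1]
            mr = (kernel * wr).sum()
            mg = (kernel * wg).sum()
            cov = (kernel * wr * wg).sum() - mr * mg
            vr = (kernel * wr * wr).sum() - mr * mr
            vg = (kernel * wg * wg).sum() - mg * mg
            if vr > eps and vg > eps:
                values[i, j] = cov / np.sqrt(vr * vg)
                defined[i, j] = True
    return np.clip(values, -1, 1), defined


def juxtaposed_blobs(n=32, sep=6, sd=2.0):
    """A red and a green blob offset along x — the contact-site archetype."""
    yy, xx = np.mgrid[0:n, 0:n]
    red = np.exp(-(((yy - 16) ** 2 + (xx - 10) ** 2)) / (2 * sd**2))
    green = np.exp(-(((yy - 16) ** 2 + (xx - 10 - sep) ** 2)) / (2 * sd**2))
    return red, green


class TestLocalCorrelationMap:
    def test_identical_images_give_plus_one(self):
        img = gaussian_filter(np.random.default_rng(0).random((32, 32)), 1.0)
        cm = local_correlation_map(img, img)
        assert cm.defined_mask.any()
        np.testing.assert_allclose(cm.values[cm.defined_mask], 1.0, atol=1e-9)

    def test_inverted_images_give_minus_one(self):
        img = gaussian_filter(np.random.default_rng(1).random((32, 32)), 1.0)
        cm = local_correlation_map(img, img.max() - img)
        np.testing.assert_allclose(cm.values[cm.defined_mask], -1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        params = CorrelationParams()
        for _ in range(3):
            red, green = rng.random((2, 48, 48))
            cm = local_correlation_map(red, green, params)
            expected, defined = gaussian_weighted_pearson(red, green, params.sigma)
            np.testing.assert_array_equal(cm.defined_mask, defined)
            np.testing.assert_allclose(cm.values[defined], expected[defined],
                                       atol=1e-9)

    def test_juxtaposed_blobs_negative_at_midpoint(self):
        red, green = juxtaposed_blobs()
        params = CorrelationParams()
        cm = local_correlation_map(red, green, params)
        assert cm.values[16, 12] < 0
        expected, _ = gaussian_weighted_pearson(red, green, params.sigma)
        assert cm.values[16, 12] == pytest.approx(expected[16, 12], abs=1e-9)

    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(3)
        red, green = rng.random((2, 24, 24))
        ab = local_correlation_map(red, green)
        ba = local_correlation_map(green, red)
        np.testing.assert_array_equal(ab.values, ba.values)

    def test_invariant_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(4)
        red, green = rng.random((2, 24, 24))
        base = local_correlation_map(red, green)
        scaled = local_correlation_map(2.5 * red + 3.0, 0.7 * green + 1.0)
        np.testing.assert_allclose(scaled.values[base.defined_mask],
                                   base.values[base.defined_mask], atol=1e-9)

    def test_constant_regions_are_undefined(self):
        cm = local_correlation_map(np.zeros((16, 16)), np.zeros((16, 16)))
        assert not cm.defined_mask.any()
        assert (cm.values == 0).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            local_correlation_map(np.zeros((4, 4)), np.zeros((5, 5)))


class TestContactMask:
    def test_nonnegative_correlation_gives_empty_mask(self):
        img = gaussian_filter(np.random.default_rng(5).random((32, 32)), 1.0)
        cm = local_correlation_map(img, img)
        assert not contact_mask(cm, img, img).any()

    def test_juxtaposed_blobs_mask_between_centers(self):
        red, green = juxtaposed_blobs()
        params = CorrelationParams()
        cm = local_correlation_map(red, green, params)
        mask = contact_mask(cm, red, green, params)
        assert mask.any()
        ys, xs = np.nonzero(mask)
        assert abs(ys.mean() - 16) < 3
        assert 10 <= xs.mean() <= 15

    def test_dim_anticorrelated_noise_is_floored_out(self):
        # a bright graded cell anchors the Otsu scale; the rest of the field
        # is perfectly anticorrelated but far below the intensity floors
        rng = np.random.default_rng(6)
        yy, xx = np.mgrid[0:32, 0:32]
        anchor = np.exp(-((yy - 5) ** 2 + (xx - 5) ** 2) / (2 * 4.0**2))
        base = gaussian_filter(rng.random((32, 32)), 1.5)
        red = np.maximum(anchor, 0.02 * base)
        green = np.maximum(anchor, 0.02 * (base.max() - base))
        params = CorrelationParams()
        cm = local_correlation_map(red, green, params)
        assert cm.values[14:, 14:].min() < -0.9  # strongly anticorrelated ...
        mask = contact_mask(cm, red, green, params)
        assert not mask[14:, 14:].any()  # ... yet excluded as dim


class TestAssignContactPairs:
    def _detection(self, coords, label, frame=0, role="red_tdt"):
        coords = np.asarray(coords)
        return Detection(frame=frame, channel_role=role, label=label,
                         y_um=float(coords[:, 0].mean()) * 0.72,
                         x_um=float(coords[:, 1].mean()) * 0.72,
                         area_um2=len(coords) * 0.72**2,
                         mean_intensity=1.0, coords=coords)

    def test_empty_mask_gives_no_pairs(self):
        assert assign_contact_pairs(np.zeros((16, 16), bool), [], []) == []

    def test_region_touching_one_mc_and_one_treg(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 7:10] = True
        mc = self._detection([[8, 4], [8, 5]], label=1)
        treg = self._detection([[8, 11], [8, 12]], label=5, role="green_egfp")
        pairs = assign_contact_pairs(mask, [mc], [treg], dilation_px=2)
        assert pairs == [(0, 1, 5)]

    def test_far_region_is_dropped(self):
        mask = np.zeros((16, 16), bool)
        mask[1, 1] = True
        mc = self._detection([[8, 4]], label=1)
        treg = self._detection([[8, 11]], label=5, role="green_egfp")
        assert assign_contact_pairs(mask, [mc], [treg], dilation_px=2) == []


class TestEventLinking:
    def test_two_adjacent_frames_make_one_short_event(self):
        events = link_contact_events([(0, 1, 2), (1, 1, 2)], 4.0)
        assert len(events) == 1
        assert events[0].duration_min == 8.0
        assert events[0].category == "short"

    def test_gap_bridging(self):
        pairs = [(f, 1, 2) for f in (3, 4, 6, 7)]
        events = link_contact_events(pairs, 4.0, max_gap=1)
        assert len(events) == 1
        assert events[0].duration_min == 20.0
        assert events[0].category == "intermediate"

    def test_long_run_is_a_long_event(self):
        pairs = [(f, 1, 2) for f in range(2, 15)]
        events = link_contact_events(pairs, 4.0)
        assert len(events) == 1
        assert events[0].duration_min == 52.0
        assert events[0].category == "long"

    def test_gap_beyond_max_gap_splits(self):
        pairs = [(0, 1, 2), (1, 1, 2), (4, 1, 2)]
        events = link_contact_events(pairs, 4.0, max_gap=1)
        assert len(events) == 2

    def test_distinct_pairs_stay_distinct(self):
        pairs = [(0, 1, 2), (0, 1, 3), (1, 1, 2)]
        events = link_contact_events(pairs, 4.0)
        assert len(events) == 2


class TestClassification:
    @pytest.mark.parametrize("duration,category", [
        (7.0, "short"),
        (10.0, "intermediate"),
        (50.0, "intermediate"),
        (52.0, "long"),
        (55.0, "long"),
    ])
    def test_bin_boundaries(self, duration, category):
        assert categorize_duration(duration) == category

    def test_counts_sum_to_events(self):
        events = [
            ContactEvent(1, 1, 0, 0, d, categorize_duration(d))
            for d in (4.0, 8.0, 20.0, 44.0, 60.0)
        ]
        counts = classify_contacts(events)
        assert counts == {"short": 2, "intermediate": 2, "long": 1}

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            categorize_duration(0.0)


class TestCorrelationParams:
    def test_window_must_be_odd_and_at_least_three(self):
        with pytest.raises(ValueError):
            CorrelationParams(window_px=4)
        with pytest.raises(ValueError):
            CorrelationParams(window_px=1)

    def test_neg_threshold_range(self):
        with pytest.raises(ValueError):
            CorrelationParams(neg_threshold=0.1)

    def test_physical_window(self):
        assert CorrelationParams().physical_window_um(0.72) == pytest.approx(3.6)
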