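"""Detector core: quarter conditions, candidate maps, pairing, assembly."""

import math

import numpy as np
import pytest

from redlesion.detection import (
    CandidateMap,
    DetectionParams,
    angle_condition,
    assemble_lesions,
    build_candidate_map,
    detect_full,
    evaluate_quarter,
    lateral_search,
    quarter_is_dark,
)
from redlesion.geometry import QUARTERS
from redlesion.synthgen import SynthParams, generate


def empty_cmap(shape):
    return CandidateMap(*(np.zeros(shape, dtype=bool) for _ in range(4)))


class TestAngleCondition:
    def test_constant_image_never_satisfies(self, params):
        g = np.full((64, 64), 0.5)
        assert not any(
            angle_condition(g, 32, 32, theta, k, params)
            for k in QUARTERS for theta in params.angles)

    def test_dark_inner_light_outer(self, params):
        g = np.full((64, 64), 0.2)
        # outer probe point for theta=0, quarter 1 sits at (32, 45)
        g[32, 45] = 0.5
        assert angle_condition(g, 32, 32, 0.0, 1, params)

    def test_light_inner_dark_outer_fails(self, params):
        g = np.full((64, 64), 0.5)
        g[32, 45] = 0.2  # farther point darker: wrong sign
        assert not angle_condition(g, 32, 32, 0.0, 1, params)

    def test_difference_below_threshold_fails(self, params):
        g = np.full((64, 64), 0.2)
        g[32, 45] = 0.25  # step of 0.05 < diff_th = 0.06
        assert not angle_condition(g, 32, 32, 0.0, 1, params)

    def test_out_of_bounds_counts_as_failed(self, params):
        g = np.zeros((64, 64))
        g[2, 12] = 1.0
        assert not angle_condition(g, 2, 2, math.pi / 2, 1, params)


class TestEvaluateQuarter:
    def test_planted_disc_satisfies_all_quarters(self, disc_image, params):
        assert all(evaluate_quarter(disc_image, 32, 32, k, params)
                   for k in QUARTERS)

    def test_vertical_bar_satisfies_no_quarter(self, bar_image, params):
        assert not any(evaluate_quarter(bar_image, 32, 32, k, params)
                       for k in QUARTERS)

    def test_uniform_image_fails(self, params):
        g = np.full((64, 64), 0.5)
        assert not any(evaluate_quarter(g, 32, 32, k, params)
                       for k in QUARTERS)

    def test_count_is_strictly_greater_than_threshold(self, disc_image):
        # with 7 angles satisfied, number_th=6 demands count > 6, i.e. all 7
        assert evaluate_quarter(disc_image, 32, 32, 1,
                                DetectionParams(number_th=6))
        # number_th=7 can never be exceeded
        with pytest.raises(ValueError):
            DetectionParams(number_th=8)


class TestQuarterIsDark:
    def test_uniform_dark(self, params):
        assert quarter_is_dark(np.full((64, 64), 0.1), 32, 32, 2, params)

    def test_uniform_light(self, params):
        assert not quarter_is_dark(np.full((64, 64), 0.9), 32, 32, 2, params)

    def test_mean_just_below_threshold(self, params):
        """A quarter averaging 0.25 (half 0.2, half 0.3) is dark at 0.28."""
        g = np.full((64, 64), 0.25)
        assert quarter_is_dark(g, 32, 32, 2, params)
        mixed = np.full((64, 64), 0.3)
        mixed[:33, :] = 0.2  # top half of the top-left quarter
        assert quarter_is_dark(mixed, 32, 32, 2, params)


class TestCandidateMap:
    def test_blank_image_all_false(self, params):
        cmap = build_candidate_map(np.full((64, 64), 0.5), None, params)
        assert cmap.total_candidates() == 0

    def test_disc_triggers_top_quarters_near_centre(self, disc_image, params):
        cmap = build_candidate_map(disc_image, None, params)
        near = np.zeros((64, 64), dtype=bool)
        near[27:38, 27:38] = True
        assert (cmap.q1 & near).any()
        assert (cmap.q2 & near).any()
        assert not (cmap.q1 & ~near).any()

    def test_skip_optimization_only_removes_bottom_candidates(self, disc_image):
        on = build_candidate_map(disc_image, None,
                                 DetectionParams(use_skip_optimization=True))
        off = build_candidate_map(disc_image, None,
                                  DetectionParams(use_skip_optimization=False))
        assert np.array_equal(on.q1, off.q1)
        assert np.array_equal(on.q2, off.q2)
        assert not (on.q3 & ~off.q3).any()
        assert not (on.q4 & ~off.q4).any()
        assert not (on.q4 & on.q1).any()

    def test_candidates_confined_to_fov(self, disc_image, params):
        fov = np.zeros((64, 64), dtype=bool)
        fov[:32, :] = True
        cmap = build_candidate_map(disc_image, fov, params)
        for k in QUARTERS:
            assert not (cmap.quarter(k) & ~fov).any()

    def test_shape_mismatch_rejected(self, disc_image, params):
        with pytest.raises(ValueError):
            build_candidate_map(disc_image, np.ones((10, 10), dtype=bool),
                                params)


class TestLateralSearch:
    def test_finds_partner_through_dark_gap(self, params):
        g = np.full((64, 64), 0.1)  # everything dark: walk never stops early
        cmap = empty_cmap(g.shape)
        cmap.q1[32, 31] = True
        cmap.q2[32, 28] = True
        match = lateral_search(g, cmap, 32, 31, 1, params)
        assert match is not None
        assert match.partner == (32, 28)
        assert match.c == 3 and match.side == "left" and match.pair == "top"

    def test_stops_on_light_quarter(self, params):
        g = np.full((64, 64), 0.9)  # light everywhere: stop at the anchor
        cmap = empty_cmap(g.shape)
        cmap.q1[32, 31] = True
        cmap.q2[32, 28] = True
        assert lateral_search(g, cmap, 32, 31, 1, params) is None

    def test_exhausts_search_cap(self, params):
        g = np.full((64, 80), 0.1)
        cmap = empty_cmap(g.shape)
        cmap.q1[32, 75] = True  # no partner anywhere within 3*a0 columns
        assert lateral_search(g, cmap, 32, 75, 1, params) is None

    def test_bottom_pair_walks_left_for_q3(self, params):
        g = np.full((64, 64), 0.1)
        cmap = empty_cmap(g.shape)
        cmap.q4[20, 40] = True
        cmap.q3[20, 36] = True
        match = lateral_search(g, cmap, 20, 40, 4, params)
        assert match is not None and match.pair == "bottom" and match.c == 4


class TestAssembleLesions:
    def test_no_candidates_empty_mask(self, params):
        g = np.full((64, 64), 0.5)
        mask = assemble_lesions(g, empty_cmap(g.shape), None, params)
        assert not mask.any()

    def test_single_disc_one_component_over_centre(self, disc_image, params):
        from scipy import ndimage
        cmap = build_candidate_map(disc_image, None, params)
        mask = assemble_lesions(disc_image, cmap, None, params)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 1
        assert mask[32, 32]

    def test_thin_vessel_produces_nothing(self, bar_image, params):
        cmap = build_candidate_map(bar_image, None, params)
        mask = assemble_lesions(bar_image, cmap, None, params)
        assert not mask.any()

    def test_bars_at_four_orientations_rejected(self, params):
        """Straight bars of width <= a0/2 are not roundish and never pair."""
        yy, xx = np.mgrid[:64, :64]
        for phi in (0, math.pi / 4, math.pi / 2, 3 * math.pi / 4):
            dist = np.abs((xx - 32) * math.sin(phi) - (yy - 32) * math.cos(phi))
            g = np.where(dist <= 2.5, 0.2, 0.7)
            cmap = build_candidate_map(g, None, params)
            mask = assemble_lesions(g, cmap, None, params)
            assert not mask.any(), f"bar at {phi:.2f} rad was detected"

    def test_mask_respects_fov(self, disc_image, params):
        fov = np.zeros((64, 64), dtype=bool)
        fov[:, :40] = True
        cmap = build_candidate_map(disc_image, fov, params)
        mask = assemble_lesions(disc_image, cmap, fov, params)
        assert not (mask & ~fov).any()


class TestInvariants:
    def test_monotone_in_diff_th(self, params):
        sample = generate(SynthParams(size=(128, 128), n_lesions=1,
                                      n_vessels=1, fov=False, seed=5))
        counts = []
        for diff_th in (0.02, 0.04, 0.06, 0.1, 0.2):
            p = DetectionParams(diff_th=diff_th)
            counts.append(build_candidate_map(sample.image, None, p)
                          .total_candidates())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_monotone_in_number_th(self):
        sample = generate(SynthParams(size=(128, 128), n_lesions=1,
                                      n_vessels=1, fov=False, seed=6))
        counts = []
        for number_th in (2, 3, 4, 5, 6):
            p = DetectionParams(number_th=number_th)
            counts.append(build_candidate_map(sample.image, None, p)
                          .total_candidates())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_angle_condition_invariant_to_additive_offset(self, params):
        rng = np.random.default_rng(11)
        g = rng.uniform(0.0, 0.5, (64, 64))
        shifted = g + 0.3
        a = build_candidate_map(g, None, params)
        b = build_candidate_map(shifted, None, params)
        assert a == b

    def test_quarter_darkness_not_invariant_to_offset(self, params):
        g = np.full((64, 64), 0.25)
        assert quarter_is_dark(g, 32, 32, 2, params)
        assert not quarter_is_dark(g + 0.1, 32, 32, 2, params)

    def test_left_right_mirror_equivariance(self, params):
        sample = generate(SynthParams(size=(128, 128), n_lesions=1,
                                      n_vessels=1, fov=False, seed=7))
        g = sample.image
        gm = g[:, ::-1].copy()
        cmap = build_candidate_map(g, None, params)
        cmapm = build_candidate_map(gm, None, params)
        assert np.array_equal(cmapm.q1[:, ::-1], cmap.q2)
        assert np.array_equal(cmapm.q4[:, ::-1], cmap.q3)
        mask = assemble_lesions(g, cmap, None, params)
        maskm = assemble_lesions(gm, cmapm, None, params)
        assert np.array_equal(maskm[:, ::-1], mask)

    def test_up_down_mirror_equivariance_without_skip(self):
        # the bottom-quarter skip couples quarters 1/4 and 2/3, which is
        # symmetric under left-right but not up-down mirroring
        p = DetectionParams(use_skip_optimization=False)
        sample = generate(SynthParams(size=(128, 128), n_lesions=1,
                                      n_vessels=1, fov=False, seed=8))
        g = sample.image
        gm = g[::-1, :].copy()
        cmap = build_candidate_map(g, None, p)
        cmapm = build_candidate_map(gm, None, p)
        assert np.array_equal(cmapm.q1[::-1, :], cmap.q4)
        assert np.array_equal(cmapm.q2[::-1, :], cmap.q3)
        mask = assemble_lesions(g, cmap, None, p)
        maskm = assemble_lesions(gm, cmapm, None, p)
        assert np.array_equal(maskm[::-1, :], mask)


class TestEndToEnd:
    def test_uniform_frame_yields_empty_mask(self, params):
        img = np.full((64, 64), 128, dtype=np.uint8)
        res = detect_full(img, params, use_fov=False)
        assert not res.mask.any()

    def test_planted_lesions_are_found(self, params):
        sample = generate(SynthParams(size=(256, 256), n_lesions=3,
                                      n_vessels=0, fov=True, seed=21,
                                      lesion_radius_range=(10.0, 13.0)))
        img = np.round(sample.image * 255).astype(np.uint8)
        res = detect_full(img, params)
        for (centre, radius, _contrast) in sample.lesion_list:
            r, c = centre
            w = int(radius)
            assert res.mask[r - w:r + w + 1, c - w:c + w + 1].any(), \
                f"lesion at {centre} (radius {radius:.1f}) missed"

    def test_detection_is_deterministic(self, params):
        sample = generate(SynthParams(size=(128, 128), n_lesions=1,
                                      n_vessels=1, seed=9))
        img = np.round(sample.image * 255).astype(np.uint8)
        a = detect_full(img, params)
        b = detect_full(img, params)
        assert np.array_equal(a.mask, b.mask)
        assert a.candidates == b.candidates

    def test_too_small_image_rejected(self, params):
        with pytest.raises(ValueError):
            detect_full(np.full((20, 20), 128, dtype=np.uint8), params)
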