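"""Structure pattern detector: circular templates, peak detection, Gabor
co-vessel responses and the fuzzy inferring function."""

import numpy as np
import pytest

from angiotrack import (PeakSet, RunConfig, detect_peaks, detect_structure,
                        fuzzy_memberships, infer_pattern, refine_node,
                        sample_template)
from angiotrack.phantom import _build_tree_centerlines
from angiotrack.spd import Peak


def peak(zhat, gabor, angle=0.0):
    az = np.array([np.cos(angle), np.sin(angle)])
    return Peak(angle=angle, position=az * 10.0, zhat=zhat, azimuth=az,
                gabor=gabor)


class TestTemplate:
    def test_fixed_sample_count_regardless_of_radius(self, phantom_a_maps, cfg):
        fmap = phantom_a_maps[0]
        for d in (4.0, 9.0, 14.0):
            t = sample_template(np.array([80.0, 60.0]), d, fmap, cfg)
            assert len(t.values) == cfg.n_circle_samples
            assert len(t.derivative) == cfg.n_circle_samples

    def test_circle_outside_image_rejected(self, phantom_a_maps, cfg):
        fmap = phantom_a_maps[0]
        with pytest.raises(ValueError, match="outside"):
            sample_template(np.array([-400.0, -400.0]), 10.0, fmap, cfg)

    def test_straight_tube_circle_has_two_peaks(self, phantom_a_maps, cfg):
        fmap = phantom_a_maps[0]
        t = sample_template(np.array([80.0, 60.0]), 13.0, fmap, cfg)
        peaks = detect_peaks(t, cfg)
        assert len(peaks) == 2
        # the two crossings lie on the tube axis: azimuths ~ 0 and pi
        angs = sorted(p.angle for p in peaks.peaks)
        assert angs[0] == pytest.approx(0.0, abs=0.15)
        assert angs[1] == pytest.approx(np.pi, abs=0.15)

    def test_constant_profile_has_no_peaks(self, cfg):
        from angiotrack.vesselness import FeatureMap

        z = np.full((64, 64), 0.5)
        fmap = FeatureMap(zhat=z, best_scale=np.ones_like(z), lam1=z, lam2=z,
                          evec1=np.zeros((64, 64, 2)), raw_max=1.0)
        t = sample_template(np.array([32.0, 32.0]), 10.0, fmap, cfg)
        assert np.allclose(t.derivative, 0.0, atol=1e-9)
        assert len(detect_peaks(t, cfg)) == 0

    def test_peak_indices_shift_with_circular_profile_shift(self, phantom_a_maps,
                                                            cfg):
        fmap = phantom_a_maps[0]
        t = sample_template(np.array([80.0, 60.0]), 13.0, fmap, cfg)
        shift = 37
        t2 = sample_template(np.array([80.0, 60.0]), 13.0, fmap, cfg)
        t2.values = np.roll(t.values, shift)
        t2.derivative = np.roll(t.derivative, shift)
        a1 = sorted(p.angle for p in detect_peaks(t, cfg).peaks)
        n = cfg.n_circle_samples
        a2 = sorted((p.angle - 2 * np.pi * shift / n) % (2 * np.pi)
                    for p in detect_peaks(t2, cfg).peaks)
        assert np.allclose(sorted(np.mod(a1, 2 * np.pi)), a2, atol=1e-6)


class TestGabor:
    def test_co_vessel_peak_scores_high(self, phantom_a, phantom_a_maps, cfg):
        _, image, _ = phantom_a
        fmap = phantom_a_maps[0]
        pr = detect_structure(np.array([80.0, 60.0]), 13.0,
                              np.array([1.0, 0.0]), fmap, image, cfg)
        assert len(pr.peak_set) == 2
        assert min(p.gabor for p in pr.peak_set.peaks) > 0.8

    def test_background_point_scores_low(self, phantom_a, phantom_a_maps, cfg):
        from angiotrack.spd import _bank_response

        _, image, _ = phantom_a
        on = _bank_response(np.array([80.0, 60.0]), 0.0, image, 13.0, cfg)
        off = _bank_response(np.array([20.0, 12.0]), 0.0, image, 13.0, cfg)
        assert off < 0.05 * on

    def test_response_bounded_in_open_unit_interval(self, phantom_a,
                                                    phantom_a_maps, cfg):
        _, image, _ = phantom_a
        fmap = phantom_a_maps[0]
        for x in (60.0, 90.0, 120.0):
            pr = detect_structure(np.array([x, 60.0]), 13.0,
                                  np.array([1.0, 0.0]), fmap, image, cfg)
            for p in pr.peak_set.peaks:
                assert 0.0 < p.gabor < 1.0


class TestFuzzyInference:
    def test_membership_formulas(self, cfg):
        peaks = PeakSet([peak(0.9, 0.8), peak(0.6, 0.8), peak(0.9, 0.5)])
        mu_z, mu_g, mu_m = fuzzy_memberships(peaks, pattern=3, cfg=cfg)
        assert mu_z[0] == pytest.approx(1.0)   # the Z-hat max peak
        assert mu_g[0] == pytest.approx(1.0)   # the gamma max peak
        assert mu_m == pytest.approx(1.0)      # M_t == i
        expected = np.exp(-((0.9 - 0.6) ** 2) / (2 * cfg.fuzzy_sigma_z**2))
        assert mu_z[1] == pytest.approx(expected)

    def test_pseudo_pattern_zero_when_too_few_peaks(self, cfg):
        peaks = PeakSet([peak(0.9, 0.9), peak(0.8, 0.9)])
        _, _, mu_m = fuzzy_memberships(peaks, pattern=3, cfg=cfg)
        assert mu_m == 0.0

    def test_no_peaks_infers_termination(self, cfg):
        res = infer_pattern(PeakSet([]), template=None, cfg=cfg)
        assert res.pattern == 1
        assert res.memberships == {1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0}

    def test_memberships_bounded_and_capped_by_count_term(self, cfg):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(1, 6))
            peaks = PeakSet([peak(rng.uniform(0.1, 1), rng.uniform(0.1, 0.99))
                             for _ in range(n)])
            res = infer_pattern(peaks, template=None, cfg=cfg)
            for i, mu in res.memberships.items():
                assert 0.0 <= mu <= 1.0
                _, _, mu_m = fuzzy_memberships(peaks, i, cfg)
                assert mu <= mu_m + 1e-12

    def test_tie_breaks_to_simpler_pattern(self, cfg):
        # two perfect co-vessel peaks: termination (i=1) and segment (i=2)
        # both reachable; segment wins because mu_M is larger, while an
        # exact tie resolves to the smaller index
        peaks = PeakSet([peak(0.9, 0.9), peak(0.9, 0.9)])
        res = infer_pattern(peaks, template=None, cfg=cfg)
        assert res.pattern == 2


class TestPatternsOnPhantoms:
    def test_straight_tube_is_segment(self, phantom_a, phantom_a_maps, cfg):
        _, image, _ = phantom_a
        fmap = phantom_a_maps[0]
        pr = detect_structure(np.array([80.0, 60.0]), 13.0,
                              np.array([1.0, 0.0]), fmap, image, cfg)
        assert pr.name == "segment"

    def test_distal_tip_is_termination(self, phantom_a, phantom_a_maps, cfg):
        _, image, _ = phantom_a
        fmap = phantom_a_maps[0]
        pr = detect_structure(np.array([150.0, 60.0]), 13.0,
                              np.array([1.0, 0.0]), fmap, image, cfg)
        assert pr.name == "termination"
        assert len(pr.peak_set) <= 1

    def test_bifurcation_and_crossing_nodes_classified(self, sat_run, cfg):
        from angiotrack.vesselness import preprocess

        spec, image, truth, _, _ = sat_run
        fmap = preprocess(image, cfg)[0]
        segs = _build_tree_centerlines(spec)
        # walk the trunk a few pixels past its first bifurcation
        trunk = segs[0]
        k = 210  # arclength ~105 px, just past the attachment at s=100
        pr = detect_structure(trunk.points[k], spec.branches[0].width,
                              trunk.tangents()[k], fmap, image, cfg)
        assert pr.name == "bifurcation"
        cross = [p for p, t in truth.nodes if t == "crossing"][0]
        pr = detect_structure(np.asarray(cross), spec.branches[3].width,
                              np.array([0.6, 0.8]), fmap, image, cfg)
        assert pr.name == "crossing"
        assert len(pr.peak_set) >= 4


class TestRefineNode:
    def test_single_detection_returned(self):
        assert np.array_equal(refine_node([np.array([3.0, 4.0])], [0.7]),
                              [3.0, 4.0])

    def test_argmax_membership_wins(self):
        pos = [np.array([0.0, 0.0]), np.array([1.0, 1.0]), np.array([2.0, 2.0])]
        assert np.array_equal(refine_node(pos, [0.6, 0.9, 0.7]), [1.0, 1.0])

    def test_empty_detections_rejected(self):
        with pytest.raises(ValueError):
            refine_node([], [])
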