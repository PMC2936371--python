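"""Probabilistic tracking operator: measures, adaptive variances and MAP
selection, including a brute-force likelihood oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiotrack import (ArteryElement, CandidateSet, NoContinuation, RunConfig,
                        adaptive_sigmas, continuity_measures, deflection_measure,
                        likelihoods, sample_candidates, sampling_disk, select_next)


def make_candidate_set(rng, n, d_t=8.0, cfg=None):
    """Random candidate set with geometry consistent with one PTO step."""
    cfg = cfg or RunConfig()
    element = ArteryElement(position=np.array([50.0, 50.0]), zhat=0.9,
                            direction=np.array([1.0, 0.0]), diameter=d_t)
    ang = rng.uniform(0, 2 * np.pi, n)
    rad = rng.uniform(2.0, d_t, n)
    pos = element.position + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    zh = rng.uniform(0.05, 1.0, n)
    dia = rng.uniform(3.0, 15.0, n)
    q_z, q_t, q_d = continuity_measures(element, pos, zh, dia,
                                        float(zh.max()), float(dia.max()))
    cand = CandidateSet(positions=pos, zhats=zh,
                        directions=np.tile([1.0, 0.0], (n, 1)), diameters=dia,
                        q_z=q_z, q_theta=q_t, q_d=q_d,
                        zhat_max=float(zh.max()), d_max=float(dia.max()))
    cand.sigmas = adaptive_sigmas(cand, cfg)
    return element, cand


class TestDeflectionMeasure:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 0.0), (math.pi, 0.0), (math.pi / 2, 0.5),
        (2 * math.pi - 1e-9, 0.0), (3 * math.pi / 2, 0.5),
    ])
    def test_reference_angles(self, theta, expected):
        assert deflection_measure(theta) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(-10.0, 10.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reversal_invariance_and_bounds(self, theta):
        q = float(deflection_measure(theta))
        assert 0.0 <= q <= 0.5 + 1e-12
        assert q == pytest.approx(float(deflection_measure(theta + math.pi)),
                                  abs=1e-9)


class TestContinuityMeasures:
    def test_extremes(self):
        element = ArteryElement(position=np.zeros(2), zhat=1.0,
                                direction=np.array([1.0, 0.0]), diameter=10.0)
        pos = np.array([[5.0, 0.0], [0.0, 5.0]])
        zh = np.array([0.8, 0.4])
        dia = np.array([10.0, 14.0])
        q_z, q_t, q_d = continuity_measures(element, pos, zh, dia, 0.8, 14.0)
        assert q_z[0] == pytest.approx(0.0)        # candidate at Z-hat max
        assert q_t[0] == pytest.approx(0.0)        # straight ahead
        assert q_t[1] == pytest.approx(0.5)        # perpendicular
        assert q_d[0] == pytest.approx(0.0)        # same diameter
        assert q_d[1] == pytest.approx(4.0 / 14.0)

    def test_measures_lie_in_unit_interval(self):
        rng = np.random.default_rng(3)
        _, cand = make_candidate_set(rng, 40)
        for q in (cand.q_z, cand.q_theta, cand.q_d):
            assert q.min() >= 0.0 and q.max() <= 1.0


class TestAdaptiveSigmas:
    def test_population_std_of_binary_measure(self, cfg):
        rng = np.random.default_rng(0)
        _, cand = make_candidate_set(rng, 2)
        cand.q_z = np.array([0.0, 1.0])
        sz, _, _ = adaptive_sigmas(cand, cfg)
        assert sz == pytest.approx(0.5)

    def test_identical_candidates_floored(self, cfg):
        rng = np.random.default_rng(0)
        _, cand = make_candidate_set(rng, 5)
        cand.q_z = np.zeros(5)
        cand.q_theta = np.zeros(5)
        cand.q_d = np.zeros(5)
        assert adaptive_sigmas(cand, cfg) == (cfg.sigma_floor,) * 3

    def test_invariant_under_candidate_reordering(self, cfg):
        rng = np.random.default_rng(5)
        _, cand = make_candidate_set(rng, 17)
        ref = adaptive_sigmas(cand, cfg)
        perm = rng.permutation(17)
        for name in ("q_z", "q_theta", "q_d"):
            setattr(cand, name, getattr(cand, name)[perm])
        assert adaptive_sigmas(cand, cfg) == pytest.approx(ref)


class TestSelectNext:
    def test_single_candidate_always_returned(self, cfg):
        rng = np.random.default_rng(1)
        _, cand = make_candidate_set(rng, 1)
        el = select_next(cand, cfg)
        assert np.array_equal(el.position, cand.positions[0])

    def test_matches_bruteforce_likelihood_oracle(self, cfg):
        # independent evaluation of the three Gaussian likelihood products,
        # written against the formulas rather than the implementation
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            _, cand = make_candidate_set(rng, int(rng.integers(2, 30)))
            scores = []
            for i in range(len(cand)):
                p = 1.0
                for q, s in zip((cand.q_z[i], cand.q_theta[i], cand.q_d[i]),
                                cand.sigmas):
                    p *= math.exp(-q * q / (2 * s * s)) / (math.sqrt(2 * math.pi) * s)
                scores.append(p)
            best = int(np.argmax(scores))
            el = select_next(cand, cfg)
            assert np.array_equal(el.position, cand.positions[best])

    def test_reversal_invariance_of_selection(self, cfg):
        # flipping the sign of the current direction leaves the MAP choice
        # unchanged (Q_theta symmetry)
        rng = np.random.default_rng(7)
        element, _ = make_candidate_set(rng, 1)
        pos = element.position + rng.uniform(-8, 8, size=(25, 2))
        zh = rng.uniform(0.1, 1.0, 25)
        dia = rng.uniform(4.0, 12.0, 25)

        def build(direction):
            el = ArteryElement(position=element.position, zhat=0.9,
                               direction=direction, diameter=8.0)
            q_z, q_t, q_d = continuity_measures(el, pos, zh, dia,
                                                float(zh.max()), float(dia.max()))
            cand = CandidateSet(positions=pos, zhats=zh,
                                directions=np.tile([1.0, 0.0], (25, 1)),
                                diameters=dia, q_z=q_z, q_theta=q_t, q_d=q_d,
                                zhat_max=float(zh.max()), d_max=float(dia.max()))
            cand.sigmas = adaptive_sigmas(cand, cfg)
            return select_next(cand, cfg)

        a = build(np.array([0.6, 0.8]))
        b = build(np.array([-0.6, -0.8]))
        assert np.array_equal(a.position, b.position)


class TestSampling:
    def test_disk_geometry_obeys_lookahead_bounds(self, cfg):
        for d in (3.0, 8.0, 13.0, 15.0, 30.0):
            el = ArteryElement(position=np.zeros(2), zhat=1.0,
                               direction=np.array([1.0, 0.0]), diameter=d)
            disk = sampling_disk(el, cfg)
            assert cfg.step_min <= disk.look_ahead <= cfg.step_max
            # integer look-ahead stays within rounding of half the diameter
            assert disk.look_ahead <= max(np.clip(d, cfg.d_min, cfg.d_max) / 2.0,
                                          cfg.step_min) + 0.5
            assert disk.radius >= disk.look_ahead

    def test_candidates_all_on_mask(self, phantom_a_maps, cfg):
        fmap, dmap, mask = phantom_a_maps[0], phantom_a_maps[1], phantom_a_maps[2]
        el = ArteryElement(position=np.array([80.0, 60.0]), zhat=1.0,
                           direction=np.array([1.0, 0.0]), diameter=13.0)
        cand = sample_candidates(el, mask, fmap, dmap, cfg)
        pix = cand.positions.astype(int)
        assert mask[pix[:, 1], pix[:, 0]].all()

    def test_background_disk_raises_no_continuation(self, phantom_a_maps, cfg):
        fmap, dmap, mask = phantom_a_maps[0], phantom_a_maps[1], phantom_a_maps[2]
        el = ArteryElement(position=np.array([15.0, 15.0]), zhat=0.0,
                           direction=np.array([1.0, 0.0]), diameter=8.0)
        with pytest.raises(NoContinuation):
            sample_candidates(el, mask, fmap, dmap, cfg)

    def test_successive_selections_advance_along_tube(self, phantom_a,
                                                      phantom_a_maps, cfg):
        _, _, truth = phantom_a
        fmap, dmap, mask = phantom_a_maps[0], phantom_a_maps[1], phantom_a_maps[2]
        el = ArteryElement(position=np.array([50.0, 60.0]), zhat=1.0,
                           direction=np.array([1.0, 0.0]), diameter=13.0)
        xs = [el.position[0]]
        for _ in range(6):
            cand = sample_candidates(el, mask, fmap, dmap, cfg,
                                     forward_only=True)
            el = select_next(cand, cfg)
            if np.dot(el.direction, [1.0, 0.0]) < 0:
                el.direction = -el.direction
            el.diameter = 13.0
            xs.append(el.position[0])
        assert np.all(np.diff(xs) > 0)
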