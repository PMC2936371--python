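"""Shared fixtures: phantoms are rendered once per session and the heavier
end-to-end runs (segment and tree tracking) are cached session-wide."""

import numpy as np
import pytest

from angiotrack import (RunConfig, SegmentPhantomSpec, default_sat_spec,
                        evaluate, preprocess, render_segment, render_tree,
                        track_tree)


@pytest.fixture(scope="session")
def cfg():
    c = RunConfig()
    c.validate()
    return c


@pytest.fixture(scope="session")
def phantom_a(cfg):
    """Uniform straight tube, width 13, blur 3.2, noise-free."""
    spec = SegmentPhantomSpec()
    image, truth = render_segment(spec, seed=0)
    return spec, image, truth


@pytest.fixture(scope="session")
def phantom_a_maps(cfg, phantom_a):
    _, image, _ = phantom_a
    return preprocess(image, cfg)


@pytest.fixture(scope="session")
def stenotic_run():
    """Full pipeline on the stenotic segment (widths 13 -> 5, blur 3.2)."""
    spec = SegmentPhantomSpec(mean_width=13, extreme_width=5, shape="stenotic")
    c = RunConfig(psf_sigma=spec.blur_sigma)
    image, truth = render_segment(spec, seed=0)
    tree = track_tree(image, c)
    metrics = evaluate(tree, truth, c)
    return spec, image, truth, tree, metrics


@pytest.fixture(scope="session")
def aneurysmal_run():
    """Full pipeline on the aneurysmal segment (widths 9 -> 18, blur 4.0)."""
    spec = SegmentPhantomSpec(mean_width=9, extreme_width=18, blur_sigma=4.0,
                              shape="aneurysmal")
    c = RunConfig(psf_sigma=spec.blur_sigma)
    image, truth = render_segment(spec, seed=0)
    tree = track_tree(image, c)
    metrics = evaluate(tree, truth, c)
    return spec, image, truth, tree, metrics


@pytest.fixture(scope="session")
def sat_run(cfg):
    """Full pipeline on the simulated arterial tree."""
    spec = default_sat_spec()
    image, truth = render_tree(spec, seed=0)
    tree = track_tree(image, cfg)
    metrics = evaluate(tree, truth, cfg)
    return spec, image, truth, tree, metrics
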