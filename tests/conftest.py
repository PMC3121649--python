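from __future__ import annotations

import numpy as np
import pytest

from neuromorph import SceneSpec, match_points, render_scene
from neuromorph.enhance import enhance
from neuromorph.pipeline import (
    detect_attachment_points,
    detect_ending_points,
    extract_neurites,
    extract_soma,
)
from neuromorph.synthetic import default_params

from _util import centroids, f1_score


@pytest.fixture(scope="session")
def params():
    return default_params()


def _recover(noise_sigma: float, gradient: float, n_scenes: int, params):
    """Run the pipeline over seeded scenes; collect per-scene recovery stats."""
    stats = []
    for seed in range(n_scenes):
        spec = SceneSpec(seed=seed, noise_sigma=noise_sigma,
                         background_gradient_amp=gradient)
        img, truth = render_scene(spec)
        i_new = enhance(img, params.enhance)
        soma, particles = extract_soma(i_new, params)
        skeleton, neurite_mask, length = extract_neurites(i_new, soma, params)
        ap_mask, _ = detect_attachment_points(soma, skeleton)
        ep_mask, _ = detect_ending_points(neurite_mask, soma)
        ap_eval = match_points(centroids(ap_mask), truth.attachment_points, 5)
        ep_eval = match_points(centroids(ep_mask), truth.ending_points, 5)
        stats.append({
            "soma_exact": len(particles) == truth.soma_count,
            "ap_f1": f1_score(ap_eval),
            "ep_f1": f1_score(ep_eval),
            "length_rel_err": abs(length - truth.total_neurite_pixel_length)
                              / truth.total_neurite_pixel_length,
        })
    return stats


@pytest.fixture(scope="session")
def recovery_noiseless(params):
    """Pipeline recovery on 20 seeded scenes without noise or gradient."""
    return _recover(0.0, 0.0, 20, params)


@pytest.fixture(scope="session")
def recovery_noisy(params):
    """Recovery at 5 gray levels of noise and a 20-gray-level gradient."""
    return _recover(5.0, 20.0, 20, params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
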