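import numpy as np
import pytest

from polarmic import SceneSpec, make_ea_scene, make_quad_scene


@pytest.fixture(scope="session")
def noiseless_ea_scene():
    """Ideal leading-edge image: disk cell, A=0.05, theta_d=90, no noise."""
    spec = SceneSpec(cell_shape="blob-with-protrusion", amplitude_A=0.05,
                     baseline_C=0.1, theta_d=90.0, noise_model="none",
                     orientation_bin_width=10.0)
    return make_ea_scene(spec)


@pytest.fixture(scope="session")
def ordered_edge_quad_scene():
    """Quad scene with ordered dipoles at the edge over a disordered body."""
    spec = SceneSpec(image_height=160, image_width=160, theta_d=60.0,
                     noise_model="gaussian", seed=7)
    return make_quad_scene(spec, p_inside=0.05, p_leading_edge=0.8,
                           theta_jitter_sd=10.0, randomize_body_theta=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
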