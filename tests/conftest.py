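"""Shared fixtures: the default noiseless phantom, its renders, and the
full pipeline result, built once per session (rendering and registration are
the expensive stages)."""

import numpy as np
import pytest

import ecgloc
from ecgloc.pipeline import PipelineConfig, localize_frames


@pytest.fixture(scope="session")
def noiseless_scene():
    return ecgloc.build_phantom()


@pytest.fixture(scope="session")
def noiseless_render(noiseless_scene):
    return ecgloc.render_views(noiseless_scene)


@pytest.fixture(scope="session")
def noiseless_frames(noiseless_render):
    return [frame for frame, _ in noiseless_render]


@pytest.fixture(scope="session")
def noiseless_detections(noiseless_render):
    return [dets for _, dets in noiseless_render]


@pytest.fixture(scope="session")
def noiseless_result(noiseless_frames, noiseless_detections):
    return localize_frames(noiseless_frames, noiseless_detections, PipelineConfig())


def surface_patch(theta_lo=-40.0, theta_hi=40.0, y_lo=-120.0, y_hi=170.0,
                  n_theta=60, n_y=60, jitter_seed=0):
    """Dense sampling of a torso patch spanning the shoulder dome.

    Including the dome keeps the registration problem well-posed (a straight
    elliptic section alone is translation-symmetric along its axis).  Sample
    positions are jittered within the grid pitch: a perfectly regular
    lattice aliases onto itself under lattice-multiple slides, which no real
    sensor sampling does.
    """
    surf = ecgloc.TorsoSurface()
    rng = np.random.default_rng(jitter_seed)
    thetas = np.linspace(theta_lo, theta_hi, n_theta)
    ys = np.linspace(y_lo, y_hi, n_y)
    dt = (theta_hi - theta_lo) / n_theta
    dy = (y_hi - y_lo) / n_y
    return np.array([
        surf.point(t + rng.uniform(-0.45, 0.45) * dt,
                   np.clip(y + rng.uniform(-0.45, 0.45) * dy, y_lo, y_hi))
        for t in thetas for y in ys
    ])
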