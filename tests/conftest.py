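import numpy as np
import pytest

from tadstruggle import kinematics as kin
from tadstruggle import synthetic as sy


@pytest.fixture(scope="session")
def struggle_body():
    """Noise-free struggling midline with attached ground truth."""
    return sy.make_tracked_movement(sy.movement_preset("struggling", seed=1))


@pytest.fixture(scope="session")
def struggle_angles(struggle_body):
    body, _ = struggle_body
    return kin.lowpass_sum(kin.compute_curvature_angles(body))


@pytest.fixture(scope="session")
def vr_pair():
    """Two-channel struggling-like traces, +53.8 mm/s imposed."""
    return sy.make_vr_traces(sy.TraceSpec(seed=3))


def circle_body(n_frames: int = 5, radius: float = 1.0, rotation: float = 0.0):
    """11 points spanning one full circle in 10 equal arcs (left turn)."""
    theta = rotation + np.arange(kin.N_POINTS) * 2 * np.pi / (kin.N_POINTS - 1)
    pts = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    pts = np.repeat(pts[None], n_frames, axis=0)
    seg = np.linalg.norm(pts[0, 1] - pts[0, 0])
    return kin.TrackedBody(times=np.arange(n_frames) / 240.0, points=pts,
                           frame_rate=240.0, body_length=10 * seg)
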