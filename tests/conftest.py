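import numpy as np
import pytest

from scatterquant import CentroidFrame, SimConfig


@pytest.fixture
def pristine_config() -> SimConfig:
    """Zero-jitter, noise-free cobblestone sheet: the score = 1 baseline."""
    return SimConfig(n_rows=10, n_cols=10, spacing=20.0, jitter_sd=0.0,
                     n_frames=5, diffusion_sd=0.0, drift_rate=0.0,
                     noise_sd=0.0, pixel_size=1.0, image_size=(256, 256),
                     seed=0)


@pytest.fixture
def square_frame() -> CentroidFrame:
    s = 10.0
    pts = np.array([[0, 0], [s, 0], [0, s], [s, s]], dtype=float)
    return CentroidFrame(frame_index=0, time_min=0.0, points=pts)


def frame_of(points) -> CentroidFrame:
    return CentroidFrame(frame_index=0, time_min=0.0,
                         points=np.asarray(points, dtype=float))
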