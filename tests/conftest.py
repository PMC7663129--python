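import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from copmat.mat_io import MatRecording
from copmat.parameters import analyze_recording
from copmat.synthetic import SynthConfig, generate_recording

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_recording(frames, grid_rows=40, grid_cols=20, sampling_rate=240.0, cell_pitch=12.7):
    """Build a MatRecording from [(frame_index, [(row, col, pressure), ...]), ...]."""
    frame_list = [
        (idx, np.array(cells, dtype=float).reshape(-1, 3)) for idx, cells in frames
    ]
    return MatRecording(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        frames=frame_list,
        sampling_rate=sampling_rate,
        cell_pitch=cell_pitch,
    )


@pytest.fixture(scope="session")
def walk16():
    """One noise-free 16-step synthetic walking trial with ground truth."""
    cfg = SynthConfig(seed=11, n_steps=16)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def walk16_analysis(walk16):
    _cfg, rec, _truth = walk16
    return analyze_recording(rec)
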