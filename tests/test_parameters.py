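"""COP trajectories and the per-subphase parameter set."""

import numpy as np
import pandas as pd
import pytest

from copmat.events import StanceEvents, build_subphases
from copmat.mat_io import MatRecording
from copmat.parameters import (
    CopTrajectory,
    InvalidFootfallError,
    PARAMETER_COLUMNS,
    analyze_recording,
    cop_of_frame,
    displacement_range,
    mean_location,
    parameter_table,
    resample_trajectory,
    subphase_parameters,
    velocity,
)
from copmat.synthetic import SynthConfig, generate_recording

from conftest import make_recording


def traj_from(points):
    """CopTrajectory from [(t_ms, x_mm, y_mm), ...] with raw == foot frame."""
    arr = np.array(points, dtype=float)
    return CopTrajectory(arr[:, 0], arr[:, 1:3], arr[:, 1:3])


# ----------------------------------------------------------------------
# per-frame COP


@pytest.mark.parametrize(
    "cells,pitch,expected",
    [
        ([(0, 0, 1.0)], 12.7, (6.35, 6.35)),
        # equal pressures at centers 6.35 and 19.05 -> midpoint
        ([(0, 0, 2.0), (0, 1, 2.0)], 12.7, (12.7, 6.35)),
        # pressures 1:3 at centers 0.5 and 10.5 (pitch 10, cols 0 and 1... )
        ([(0, 0, 1.0), (0, 1, 3.0)], 10.0, (12.5, 5.0)),
    ],
)
def test_cop_of_frame_weighted_centroid(cells, pitch, expected):
    assert cop_of_frame(np.array(cells, float), pitch) == pytest.approx(expected)


def test_cop_of_frame_zero_pressure_is_undefined():
    assert cop_of_frame(np.array([[0, 0, 0.0]]), 12.7) is None
    assert cop_of_frame(np.empty((0, 3)), 12.7) is None


# ----------------------------------------------------------------------
# interval parameters


def test_displacement_range_examples():
    traj = traj_from([(0, 0, 0), (10, 3, 5), (20, 1, 9)])
    assert displacement_range(traj, (0, 20), "ML") == 3.0
    assert displacement_range(traj, (0, 20), "AP") == 9.0
    assert displacement_range(traj, (0, 0), "ML") == 0.0  # single sample
    assert displacement_range(traj, (30, 40), "ML") is None  # empty interval


def test_range_monotone_under_interval_inclusion():
    rng = np.random.default_rng(3)
    pts = [(float(10 * i), float(rng.normal()), float(rng.normal())) for i in range(50)]
    traj = traj_from(pts)
    whole = displacement_range(traj, (0, 490), "AP")
    for a, b in [(0, 100), (100, 300), (200, 490)]:
        assert displacement_range(traj, (a, b), "AP") <= whole + 1e-12


def test_mean_location_signed_percentages():
    traj = traj_from([(0, 0, -18.6), (10, 0, -18.6)])
    assert mean_location(traj, (0, 10), "AP", foot_length=250.0, foot_width=100.0) == (
        pytest.approx(-7.44)
    )
    assert mean_location(traj, (0, 10), "ML", 250.0, 100.0) == pytest.approx(0.0)
    traj2 = traj_from([(0, 5.0, 0), (10, 5.0, 0)])
    assert mean_location(traj2, (0, 10), "ML", 250.0, 100.0) == pytest.approx(5.0)
    assert mean_location(traj2, (50, 60), "ML", 250.0, 100.0) is None


def test_velocity_3_4_5_triangle():
    traj = traj_from([(0, 0, 0), (10, 3, 4), (20, 3, 4)])
    assert velocity(traj, (0, 20), "ML") == pytest.approx(15.0)
    assert velocity(traj, (0, 20), "AP") == pytest.approx(20.0)
    assert velocity(traj, (0, 20), "total") == pytest.approx(25.0)


def test_velocity_degenerate_cases():
    stationary = traj_from([(0, 1, 2), (10, 1, 2), (20, 1, 2)])
    for ax in ("ML", "AP", "total"):
        assert velocity(stationary, (0, 20), ax) == 0.0
    one_d = traj_from([(0, 2, 0), (10, 2, 7), (20, 2, 11)])
    assert velocity(one_d, (0, 20), "total") == pytest.approx(
        velocity(one_d, (0, 20), "AP")
    )
    assert velocity(one_d, (15, 15), "AP") is None  # zero-length interval
    assert velocity(one_d, (0, 5), "AP") is None  # < 2 samples inside


def test_velocity_net_mode_uses_endpoints():
    traj = traj_from([(0, 0, 0), (10, 3, 0), (20, 0, 0)])
    assert velocity(traj, (0, 20), "ML", mode="path") == pytest.approx(30.0)
    assert velocity(traj, (0, 20), "ML", mode="net") == pytest.approx(0.0)


def test_step_attributed_to_interval_of_later_sample():
    traj = traj_from([(0, 0, 0), (10, 1, 0), (20, 3, 0), (30, 6, 0)])
    # interval (10, 30]: steps ending at 20 and 30 -> |2| + |3| over 20 ms
    assert velocity(traj, (10, 30), "ML") == pytest.approx((2 + 3) / 20 * 100)
    # the step ending exactly at 10 belongs to the earlier interval
    assert velocity(traj, (0, 10), "ML") == pytest.approx(1 / 10 * 100)


def test_triangle_inequality_per_subphase(walk16_analysis):
    for _, row in walk16_analysis.parameters.iterrows():
        for sp in ("ICP", "LCP", "FFP", "CbP", "IPP", "LPP"):
            vml, vap, vtot = (
                row[f"{sp}_velML_cms"], row[f"{sp}_velAP_cms"], row[f"{sp}_velTot_cms"]
            )
            if np.isnan(vtot):
                continue
            assert max(vml, vap) <= vtot + 1e-9
            assert vtot <= vml + vap + 1e-9


# ----------------------------------------------------------------------
# resampling


def test_resample_linear_trajectory_is_linear():
    traj = traj_from([(0, 0, 0), (100, 0, 100)])
    out = resample_trajectory(traj, n_points=100)
    assert np.allclose(out["y"], np.linspace(0, 100, 100))
    assert np.allclose(out["x"], 0.0)


def test_resample_uniform_identity_and_normalisation():
    t = np.linspace(0, 99, 100)
    y = np.sqrt(np.linspace(0, 1, 100)) * 200
    traj = CopTrajectory(t, np.column_stack([t * 0, y]), np.column_stack([t * 0, y]))
    out = resample_trajectory(traj, n_points=100)
    assert np.allclose(out["y"], y, atol=1e-9)
    norm = resample_trajectory(traj, n_points=100, foot_length=200.0, foot_width=100.0)
    assert np.allclose(norm["y"], y / 2.0, atol=1e-9)


# ----------------------------------------------------------------------
# whole-footfall parameters and tables


def test_constant_trajectory_parameters_are_flat():
    ev = StanceEvents(0.0, 50.0, 150.0, 300.0, 450.0, 500.0)
    t = np.arange(0.0, 501.0, 1000.0 / 240.0)
    xy = np.tile([4.0, 30.0], (len(t), 1))
    traj = CopTrajectory(t, xy, xy)
    params = subphase_parameters(traj, ev, foot_length=250.0, foot_width=100.0)
    for sp in ("ICP", "LCP", "FFP", "CbP", "IPP", "LPP"):
        assert params[f"{sp}_rangeML_mm"] == 0.0
        assert params[f"{sp}_velTot_cms"] == 0.0
        assert params[f"{sp}_mlocML_pct"] == pytest.approx(4.0)
    total = sum(params[f"{sp}_dur_pct"] for sp in ("ICP", "LCP", "FFP", "IPP", "LPP"))
    assert total == pytest.approx(100.0, abs=1e-9)


def test_mirrored_recording_gives_identical_ml_parameters(walk16):
    """Mirroring the whole mat flips sides but leaves foot-frame params unchanged."""
    _cfg, rec, _truth = walk16
    mirrored_frames = []
    for idx, cells in rec.frames:
        flipped = cells.copy()
        flipped[:, 1] = rec.grid_cols - 1 - flipped[:, 1]
        mirrored_frames.append((idx, flipped))
    mirrored = MatRecording(
        grid_rows=rec.grid_rows, grid_cols=rec.grid_cols, frames=mirrored_frames,
        sampling_rate=rec.sampling_rate, cell_pitch=rec.cell_pitch,
    )
    a1 = analyze_recording(rec).parameters
    a2 = analyze_recording(mirrored).parameters
    assert list(a1["side"]) == [
        {"left": "right", "right": "left"}[s] for s in a2["side"]
    ]
    for col in PARAMETER_COLUMNS:
        assert np.allclose(a1[col], a2[col], equal_nan=True, atol=1e-6), col


def test_trajectory_progresses_heel_to_toe(walk16, walk16_analysis):
    for traj in walk16_analysis.trajectories:
        y = traj.foot[:, 1]
        assert y[-1] > y[0]
        # no large backward excursions on a noise-free rollover
        assert np.min(np.diff(y)) > -5.0


def test_too_few_cop_samples_is_invalid():
    with pytest.raises(InvalidFootfallError):
        CopTrajectory(np.array([0.0]), np.array([[0, 0]]), np.array([[0, 0]]))


def test_parameter_table_side_filter_and_empty():
    cfg = SynthConfig(seed=5, n_steps=8)
    rec, _truth = generate_recording(cfg)
    table = parameter_table({("S1", "comfortable"): rec}, side="right")
    assert 0 < len(table) <= 8
    assert set(table["side"]) == {"right"}
    empty = parameter_table({})
    assert len(empty) == 0
    assert list(empty.columns[:4]) == ["subject", "condition", "side", "footfall"]
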