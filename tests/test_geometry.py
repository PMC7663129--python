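"""Footfall clustering, side assignment, foot-axis estimation and Eq.-style rotation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copmat.geometry import (
    DegenerateFootfallError,
    FootAxis,
    Footfall,
    assign_sides,
    detect_footfalls,
    estimate_axis,
    transform_point,
    transform_points,
)

from conftest import make_recording


def block_footfall(rows, cols, on_ms=0.0, off_ms=100.0, row0=0, col0=0):
    cells = {
        (row0 + r, col0 + c): (on_ms, off_ms) for r in range(rows) for c in range(cols)
    }
    return Footfall(cells)


# ----------------------------------------------------------------------
# detection


def test_single_cluster_is_one_footfall(walk16):
    _cfg, rec, truth = walk16
    footfalls = detect_footfalls(rec)
    assert len(footfalls) == truth.n_footfalls == 16
    # first-contact order matches the planted step order
    for ff, tf in zip(footfalls, truth.footfalls):
        assert set(ff.cells) == tf.cell_set
        assert ff.first_contact_ms == pytest.approx(tf.events.fct_ms, abs=1e-9)


def test_two_separated_clusters():
    frames = []
    for f in range(5):
        cells = [(r, c, 1.0) for r in range(3) for c in range(3)]
        cells += [(r + 20, c, 1.0) for r in range(3) for c in range(3)]
        frames.append((f, cells))
    rec = make_recording(frames)
    assert len(detect_footfalls(rec)) == 2


def test_small_clusters_discarded_and_gaps_bridged():
    base = [(0, 0, 1.0), (0, 1, 1.0), (1, 0, 1.0), (1, 1, 1.0), (2, 0, 1.0)]
    frames = [
        (0, base),
        # 2-frame gap; a lone far-away cell never reaches min_cells
        (3, base + [(30, 10, 1.0)]),
    ]
    rec = make_recording(frames)
    ffs = detect_footfalls(rec, min_cells=5, max_gap=2)
    assert len(ffs) == 1
    assert (30, 10) not in ffs[0].cells
    # with max_gap=1 the 2-frame gap splits the cluster in time, but both
    # halves have the same 5 cells, still one spatial cluster each
    ffs2 = detect_footfalls(rec, min_cells=5, max_gap=1)
    assert len(ffs2) == 2


# ----------------------------------------------------------------------
# sides


def test_two_footfalls_sided_by_lateral_offset():
    left = block_footfall(4, 3, col0=0)
    right = block_footfall(4, 3, on_ms=200, off_ms=300, row0=10, col0=10)
    sides = assign_sides([left, right], cell_pitch=12.7)
    assert sides == ["left", "right"]


def test_single_footfall_unknown():
    ff = block_footfall(4, 3)
    assert assign_sides([ff], cell_pitch=12.7) == ["unknown"]


def test_cohort_sides_match_ground_truth(walk16, walk16_analysis):
    _cfg, _rec, truth = walk16
    assert list(walk16_analysis.footfalls["side"]) == truth.sides


def test_non_alternating_geometry_flagged_unknown():
    # both interior footfalls bulge to the same side of the path, so no
    # alternating left/right labelling is geometrically consistent
    offsets = [0, 3, 3, 0]
    ffs = [
        block_footfall(4, 3, on_ms=100 * i, off_ms=100 * i + 80, row0=8 * i, col0=off)
        for i, off in enumerate(offsets)
    ]
    sides = assign_sides(ffs, cell_pitch=12.7)
    assert set(sides) == {"unknown"}


# ----------------------------------------------------------------------
# axis estimation


def test_vertical_block_axis():
    """3x9 vertical block at 10 mm pitch: theta_c 0, L=90, W=30, H below T."""
    ff = block_footfall(9, 3)
    axis = estimate_axis(ff, cell_pitch=10.0)
    assert axis.theta_c == pytest.approx(0.0, abs=1e-12)
    assert axis.foot_length == pytest.approx(90.0)
    assert axis.foot_width == pytest.approx(30.0)
    assert axis.heel[1] < axis.toe[1]
    assert {len(axis.thirds[t]) for t in ("proximal", "middle", "distal")} == {9}


def test_diagonal_block_axis_maps_toe_to_y():
    """A 45-degree strip: |theta_c| = 45 deg and T lands on (0, |HT|)."""
    cells = {
        (r, c): (0.0, 100.0)
        for r in range(12)
        for c in range(12)
        if abs(r - c) <= 1
    }
    ff = Footfall(cells)
    axis = estimate_axis(ff, cell_pitch=10.0)
    assert abs(axis.theta_c) == pytest.approx(math.pi / 4, abs=1e-6)
    x, y = transform_point(axis.toe, axis)
    assert x == pytest.approx(0.0, abs=1e-9)
    assert y == pytest.approx(axis.heel_toe_distance, abs=1e-9)


def test_mirrored_footfall_flips_theta_sign():
    cells = {(r, c): (0.0, 100.0) for r in range(12) for c in range(12) if abs(r - c) <= 1}
    mirrored = {(r, 11 - c): t for (r, c), t in cells.items()}
    a1 = estimate_axis(Footfall(cells), 10.0)
    a2 = estimate_axis(Footfall(mirrored), 10.0)
    assert a1.theta_c == pytest.approx(-a2.theta_c, abs=1e-9)


def test_estimated_toe_always_maps_to_positive_y(walk16_analysis):
    for _, row in walk16_analysis.footfalls.iterrows():
        axis = FootAxis(
            heel=np.array([row["heel_e_mm"], row["heel_f_mm"]]),
            toe=np.array([row["toe_c_mm"], row["toe_d_mm"]]),
            theta_o=0.0,
            theta_c=math.radians(row["theta_c_deg"]),
            foot_length=row["foot_length_mm"],
            foot_width=row["foot_width_mm"],
        )
        x, y = transform_point(axis.toe, axis)
        assert x == pytest.approx(0.0, abs=1e-9)
        assert y == pytest.approx(axis.heel_toe_distance, abs=1e-9)


def test_thirds_partition(walk16):
    _cfg, rec, _truth = walk16
    for ff in detect_footfalls(rec):
        axis = estimate_axis(ff, rec.cell_pitch)
        groups = [axis.thirds[k] for k in ("proximal", "middle", "distal")]
        assert sum(len(g) for g in groups) == ff.n_cells
        assert not (groups[0] & groups[1] or groups[1] & groups[2] or groups[0] & groups[2])


def test_degenerate_footfalls_raise():
    with pytest.raises(DegenerateFootfallError):
        estimate_axis(Footfall({(0, 0): (0, 1), (0, 1): (0, 1)}), 10.0)


# ----------------------------------------------------------------------
# the rotation into the foot frame


def test_transform_heel_is_origin():
    axis = FootAxis(
        heel=np.array([10.0, 20.0]), toe=np.array([10.0, 120.0]),
        theta_o=math.pi / 2, theta_c=0.0, foot_length=110.0, foot_width=40.0,
    )
    assert transform_point((10.0, 20.0), axis) == pytest.approx((0.0, 0.0))
    # pure translation when theta_c = 0
    assert transform_point((13.0, 50.0), axis) == pytest.approx((3.0, 30.0))


def test_transform_45_degree_example():
    axis = FootAxis(
        heel=np.array([0.0, 0.0]), toe=np.array([100.0, 100.0]),
        theta_o=math.atan2(100, 100), theta_c=math.atan2(100, 100),
        foot_length=150.0, foot_width=50.0,
    )
    x, y = transform_point((100.0, 100.0), axis, side="right")
    assert (x, y) == pytest.approx((0.0, math.sqrt(2) * 100), abs=1e-9)


def test_left_side_mirrors_x_only():
    axis = FootAxis(
        heel=np.array([0.0, 0.0]), toe=np.array([0.0, 100.0]),
        theta_o=math.pi / 2, theta_c=0.0, foot_length=110.0, foot_width=40.0,
    )
    xr, yr = transform_point((5.0, 30.0), axis, side="right")
    xl, yl = transform_point((5.0, 30.0), axis, side="left")
    assert (xl, yl) == pytest.approx((-xr, yr))


@given(
    theta=st.floats(-math.pi, math.pi),
    heel=st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
    p=st.tuples(st.floats(-500, 500), st.floats(-500, 500)),
    q=st.tuples(st.floats(-500, 500), st.floats(-500, 500)),
)
def test_transform_is_isometry(theta, heel, p, q):
    """Distances are preserved by the rotation (before any mirroring)."""
    heel = np.array(heel)
    toe = heel + 100.0 * np.array([math.sin(theta), math.cos(theta)])
    axis = FootAxis(heel=heel, toe=toe, theta_o=0.0, theta_c=theta,
                    foot_length=100.0, foot_width=40.0)
    pts = np.array([p, q])
    out = transform_points(pts, axis)
    d_raw = np.hypot(*(pts[0] - pts[1]))
    d_foot = np.hypot(*(out[0] - out[1]))
    assert d_foot == pytest.approx(d_raw, abs=1e-6, rel=1e-9)
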