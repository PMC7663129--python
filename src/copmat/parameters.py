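"""Foot-frame COP trajectories and the per-footfall parameter set.

For every frame between first and last contact of a footfall, the COP is
the pressure-weighted centroid of the footfall's active cell centers
(binary recordings reduce to the geometric centroid).  The raw mat-frame
samples are rotated into the foot frame (origin at the heel center, +y
heel-to-toe, +x medial-to-lateral) and then parameterised per subphase:

* duration as % of stance,
* mediolateral/anteroposterior displacement ranges (mm, max minus min),
* mean COP locations as % of foot width (ML) and foot length (AP) — signed,
  since the COP may start behind or medial to the heel center,
* ML/AP/total velocities (cm/s), defined as path length over duration: the
  sum of |dx|, |dy| or Euclidean step lengths between consecutive samples,
  divided by the subphase duration.  A net-displacement variant is
  available via ``velocity_mode="net"``.

Interval membership is closed on both ends; a step between two samples is
attributed to the subphase containing the later sample, so every step is
counted exactly once across the five exhaustive subphases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import (
    EVENT_NAMES,
    SUBPHASE_BOUNDS,
    StanceEvents,
    build_subphases,
    detect_events,
    normalize_events,
)
from .geometry import (
    DegenerateFootfallError,
    FootAxis,
    Footfall,
    assign_sides,
    detect_footfalls,
    estimate_axis,
    transform_points,
)
from .mat_io import MatRecording

__all__ = [
    "InvalidFootfallError",
    "CopTrajectory",
    "cop_of_frame",
    "build_trajectory",
    "displacement_range",
    "mean_location",
    "velocity",
    "resample_trajectory",
    "subphase_parameters",
    "analyze_recording",
    "parameter_table",
    "PARAMETER_COLUMNS",
]

MM_PER_MS_TO_CM_PER_S = 100.0  # 1 mm/ms = 1 m/s = 100 cm/s


class InvalidFootfallError(ValueError):
    """Footfall cannot produce a usable trajectory (e.g. < 2 COP samples)."""


@dataclass
class CopTrajectory:
    """Time-stamped COP samples of one footfall in mat and foot frames (mm)."""

    times_ms: np.ndarray  # (N,)
    raw: np.ndarray  # (N, 2) mat frame (a, b)
    foot: np.ndarray  # (N, 2) foot frame (x, y)
    footfall_index: int = 0
    side: str = "unknown"

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float).reshape(-1, 2)
        self.foot = np.asarray(self.foot, dtype=float).reshape(-1, 2)
        if len(self.times_ms) < 2:
            raise InvalidFootfallError("trajectory needs >= 2 samples")
        if (np.diff(self.times_ms) <= 0).any():
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_ms)

    def axis_values(self, axis: str) -> np.ndarray:
        if axis == "ML":
            return self.foot[:, 0]
        if axis == "AP":
            return self.foot[:, 1]
        raise ValueError(f"axis must be 'ML' or 'AP', got {axis!r}")


def cop_of_frame(cells: np.ndarray, cell_pitch: float) -> tuple[float, float] | None:
    """Pressure-weighted centroid (a, b) in mm of one frame's active cells.

    Returns ``None`` when the total pressure is zero (no COP is defined).
    """
    arr = np.asarray(cells, dtype=float).reshape(-1, 3)
    if arr.shape[0] == 0:
        return None
    total = arr[:, 2].sum()
    if total <= 0:
        return None
    a = ((arr[:, 1] + 0.5) * cell_pitch * arr[:, 2]).sum() / total
    b = ((arr[:, 0] + 0.5) * cell_pitch * arr[:, 2]).sum() / total
    return float(a), float(b)


def build_trajectory(
    rec: MatRecording, ff: Footfall, axis: FootAxis, side: str | None = None
) -> CopTrajectory:
    """COP trajectory of one footfall, restricted to the footfall's own cells.

    Frames between the footfall's first and last contact contribute one
    sample each when at least one of the footfall's cells carries pressure.
    Raises :class:`InvalidFootfallError` with fewer than two samples.
    """
    side = side or ff.side
    mirror = "left" if side == "left" else "right"
    cell_set = set(ff.cells)
    t0, t1 = ff.first_contact_ms, ff.last_contact_ms
    times, raws = [], []
    for idx, cells in rec.frames:
        t = rec.frame_time_ms(idx)
        if t < t0 or t > t1 or cells.shape[0] == 0:
            continue
        mask = np.array(
            [(int(r), int(c)) in cell_set for r, c in cells[:, :2]], dtype=bool
        )
        if not mask.any():
            continue
        cop = cop_of_frame(cells[mask], rec.cell_pitch)
        if cop is None:
            continue
        times.append(t)
        raws.append(cop)
    if len(times) < 2:
        raise InvalidFootfallError(
            f"footfall {ff.index}: only {len(times)} COP samples"
        )
    raw = np.array(raws)
    foot = transform_points(raw, axis, mirror)
    return CopTrajectory(
        np.array(times), raw, foot, footfall_index=ff.index, side=side
    )


# ----------------------------------------------------------------------
# per-interval parameters


_TIME_TOL_MS = 1e-6  # fp slack for samples meant to sit exactly on an event


def _in_interval(traj: CopTrajectory, interval: tuple[float, float]) -> np.ndarray:
    t0, t1 = interval
    return (traj.times_ms >= t0 - _TIME_TOL_MS) & (traj.times_ms <= t1 + _TIME_TOL_MS)


def displacement_range(
    traj: CopTrajectory, interval: tuple[float, float], axis: str
) -> float | None:
    """max - min of the ML (x) or AP (y) coordinate over the closed interval, mm."""
    mask = _in_interval(traj, interval)
    if not mask.any():
        return None
    vals = traj.axis_values(axis)[mask]
    return float(np.ptp(vals))


def mean_location(
    traj: CopTrajectory,
    interval: tuple[float, float],
    axis: str,
    foot_length: float,
    foot_width: float,
) -> float | None:
    """Mean COP location over the interval, as a signed % of foot width/length."""
    if foot_length <= 0 or foot_width <= 0:
        raise ValueError("foot dimensions must be positive")
    mask = _in_interval(traj, interval)
    if not mask.any():
        return None
    mean = float(traj.axis_values(axis)[mask].mean())
    denom = foot_width if axis == "ML" else foot_length
    return 100.0 * mean / denom


def velocity(
    traj: CopTrajectory,
    interval: tuple[float, float],
    axis: str,
    mode: str = "path",
) -> float | None:
    """Mean COP speed over the interval in cm/s.

    ``axis`` is ``"ML"``, ``"AP"`` or ``"total"``.  In ``"path"`` mode the
    numerator is the summed |dx|, |dy| or Euclidean step length over
    consecutive sample pairs whose later sample falls in (t0, t1]; in
    ``"net"`` mode it is the straight-line displacement between the first
    and last sample inside the interval.
    """
    t0, t1 = interval
    if t1 <= t0:
        return None
    mask = _in_interval(traj, interval)
    if mask.sum() < 2:
        return None
    dx = np.diff(traj.foot[:, 0])
    dy = np.diff(traj.foot[:, 1])
    if mode == "path":
        later = traj.times_ms[1:]
        sel = (later > t0 + _TIME_TOL_MS) & (later <= t1 + _TIME_TOL_MS)
        if axis == "ML":
            dist = np.abs(dx[sel]).sum()
        elif axis == "AP":
            dist = np.abs(dy[sel]).sum()
        elif axis == "total":
            dist = np.hypot(dx[sel], dy[sel]).sum()
        else:
            raise ValueError(f"axis must be ML, AP or total, got {axis!r}")
    elif mode == "net":
        idx = np.flatnonzero(mask)
        vx = traj.foot[idx[-1], 0] - traj.foot[idx[0], 0]
        vy = traj.foot[idx[-1], 1] - traj.foot[idx[0], 1]
        if axis == "ML":
            dist = abs(vx)
        elif axis == "AP":
            dist = abs(vy)
        elif axis == "total":
            dist = float(np.hypot(vx, vy))
        else:
            raise ValueError(f"axis must be ML, AP or total, got {axis!r}")
    else:
        raise ValueError(f"mode must be 'path' or 'net', got {mode!r}")
    return float(dist) / (t1 - t0) * MM_PER_MS_TO_CM_PER_S


def resample_trajectory(
    traj: CopTrajectory,
    n_points: int = 100,
    foot_length: float | None = None,
    foot_width: float | None = None,
) -> pd.DataFrame:
    """Linearly interpolate the trajectory at equally spaced % of stance.

    Returns a DataFrame with columns ``pct, x, y``.  If foot dimensions are
    given, x and y are normalised to % of foot width and length (used for
    cohort-mean trajectory plots); otherwise they stay in mm.
    """
    pct = np.linspace(0.0, 100.0, n_points)
    t = traj.times_ms[0] + pct / 100.0 * (traj.times_ms[-1] - traj.times_ms[0])
    x = np.interp(t, traj.times_ms, traj.foot[:, 0])
    y = np.interp(t, traj.times_ms, traj.foot[:, 1])
    if foot_width is not None:
        x = 100.0 * x / foot_width
    if foot_length is not None:
        y = 100.0 * y / foot_length
    return pd.DataFrame({"pct": pct, "x": x, "y": y})


# ----------------------------------------------------------------------
# assembled per-footfall parameter set

_SUBPHASE_ORDER = ("ICP", "LCP", "FFP", "CbP", "IPP", "LPP")
_TIMEPOINT_COLS = ("MON_pct", "FFT_pct", "HOT_pct", "MOF_pct")


def _subphase_cols() -> list[str]:
    cols = []
    for sp in _SUBPHASE_ORDER:
        cols += [
            f"{sp}_dur_pct",
            f"{sp}_rangeML_mm",
            f"{sp}_rangeAP_mm",
            f"{sp}_mlocML_pct",
            f"{sp}_mlocAP_pct",
            f"{sp}_velML_cms",
            f"{sp}_velAP_cms",
            f"{sp}_velTot_cms",
        ]
    return cols


PARAMETER_COLUMNS = ["stance_ms", *_TIMEPOINT_COLS, *_subphase_cols()]


def subphase_parameters(
    traj: CopTrajectory,
    events: StanceEvents,
    foot_length: float,
    foot_width: float,
    velocity_mode: str = "path",
) -> dict[str, float]:
    """All temporal, spatial and velocity parameters of one footfall.

    Missing values (empty subphases, e.g. when two events coincide) are
    reported as NaN, never fabricated.
    """
    pct = normalize_events(events)
    subphases = build_subphases(events)
    out: dict[str, float] = {"stance_ms": events.stance_ms}
    for name in _TIMEPOINT_COLS:
        out[name] = pct[name[:3]]
    for sp in _SUBPHASE_ORDER:
        iv = subphases.interval(sp)
        out[f"{sp}_dur_pct"] = subphases.duration_pct[sp]
        for ax, tag in (("ML", "rangeML_mm"), ("AP", "rangeAP_mm")):
            v = displacement_range(traj, iv, ax)
            out[f"{sp}_{tag}"] = np.nan if v is None else v
        for ax, tag in (("ML", "mlocML_pct"), ("AP", "mlocAP_pct")):
            v = mean_location(traj, iv, ax, foot_length, foot_width)
            out[f"{sp}_{tag}"] = np.nan if v is None else v
        for ax, tag in (("ML", "velML_cms"), ("AP", "velAP_cms"), ("total", "velTot_cms")):
            v = velocity(traj, iv, ax, mode=velocity_mode)
            out[f"{sp}_{tag}"] = np.nan if v is None else v
    return out


@dataclass
class RecordingAnalysis:
    """Outputs of the full single-recording pipeline."""

    parameters: pd.DataFrame  # one row per valid footfall
    footfalls: pd.DataFrame  # geometry + events for every detected footfall
    trajectories: list[CopTrajectory]
    exclusions: list[tuple[int, str]]  # (footfall index, reason)


def analyze_recording(
    rec: MatRecording,
    subject: str | None = None,
    condition: str | None = None,
    min_cells: int = 5,
    max_gap: int = 2,
    fft_rule: str = "cumulative",
    velocity_mode: str = "path",
) -> RecordingAnalysis:
    """Run footfall detection, axis estimation, events and parameters.

    Footfalls that are degenerate, have non-monotone events or too few COP
    samples are excluded from the parameter table and listed (with reasons)
    in ``exclusions``; they still appear in the ``footfalls`` table with
    ``valid=False``.
    """
    footfalls = detect_footfalls(rec, min_cells=min_cells, max_gap=max_gap)
    assign_sides(footfalls, rec.cell_pitch, rec.walking_axis)

    geo_rows, param_rows, trajectories, exclusions = [], [], [], []
    for ff in footfalls:
        row: dict = {
            "footfall_index": ff.index,
            "side": ff.side,
            "first_contact_ms": ff.first_contact_ms,
            "last_contact_ms": ff.last_contact_ms,
            "n_cells": ff.n_cells,
            "valid": False,
            "reason": None,
        }
        try:
            axis = estimate_axis(ff, rec.cell_pitch, rec.walking_axis)
        except DegenerateFootfallError as exc:
            row["reason"] = str(exc)
            geo_rows.append(row)
            exclusions.append((ff.index, str(exc)))
            continue
        row.update(
            theta_c_deg=np.degrees(axis.theta_c),
            foot_length_mm=axis.foot_length,
            foot_width_mm=axis.foot_width,
            heel_e_mm=axis.heel[0],
            heel_f_mm=axis.heel[1],
            toe_c_mm=axis.toe[0],
            toe_d_mm=axis.toe[1],
        )
        try:
            ev = detect_events(ff, axis, fft_rule=fft_rule)
        except ValueError as exc:
            row["reason"] = str(exc)
            geo_rows.append(row)
            exclusions.append((ff.index, str(exc)))
            continue
        for name in EVENT_NAMES:
            row[f"{name}_ms"] = ev.time_ms(name)
        if not ev.valid:
            reason = f"non-monotone events ({ev.reason})"
            row["reason"] = reason
            geo_rows.append(row)
            exclusions.append((ff.index, reason))
            continue
        try:
            traj = build_trajectory(rec, ff, axis)
        except InvalidFootfallError as exc:
            row["reason"] = str(exc)
            geo_rows.append(row)
            exclusions.append((ff.index, str(exc)))
            continue
        row["valid"] = True
        geo_rows.append(row)
        trajectories.append(traj)
        params = subphase_parameters(
            traj, ev, axis.foot_length, axis.foot_width, velocity_mode=velocity_mode
        )
        param_rows.append(
            {
                "subject": subject,
                "condition": condition,
                "side": ff.side,
                "footfall": ff.index,
                **params,
            }
        )

    param_df = pd.DataFrame(
        param_rows,
        columns=["subject", "condition", "side", "footfall", *PARAMETER_COLUMNS],
    )
    geo_df = pd.DataFrame(geo_rows)
    return RecordingAnalysis(param_df, geo_df, trajectories, exclusions)


def parameter_table(
    recordings: dict[tuple[str, str], MatRecording],
    side: str | dict[str, str] | None = None,
    **analysis_kwargs,
) -> pd.DataFrame:
    """Concatenate per-recording parameter tables over a cohort.

    ``recordings`` maps ``(subject, condition)`` to a recording.  ``side``
    restricts the table: a single label keeps that side everywhere, a
    ``{subject: side}`` mapping keeps each subject's (typically dominant)
    side, ``None`` keeps all footfalls.
    """
    tables = []
    for (subject, condition), rec in recordings.items():
        analysis = analyze_recording(
            rec, subject=subject, condition=condition, **analysis_kwargs
        )
        df = analysis.parameters
        if isinstance(side, str):
            df = df[df["side"] == side]
        elif isinstance(side, dict):
            df = df[df["side"] == side.get(subject)]
        tables.append(df)
    if not tables:
        return pd.DataFrame(
            columns=["subject", "condition", "side", "footfall", *PARAMETER_COLUMNS]
        )
    return pd.concat(tables, ignore_index=True)
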