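"""Footfall segmentation and per-footfall foot-axis geometry.

A footfall is one complete foot–mat contact.  Cells are clustered into
footfalls by spatial 8-connectivity combined with temporal overlap (gaps of
at most ``max_gap`` frames are bridged, so a flickering sensor stays inside
its footfall).  For each footfall a foot axis is estimated: the cells are
split into proximal/middle/distal thirds along the foot's long axis, the
heel center H is the centroid of the proximal third and the toe center T
the centroid of the distal third, and the signed angle theta_c between the
mat's axis of progression and the heel-to-toe line defines a rigid rotation
that maps mat coordinates into a foot frame with origin H and +y pointing
from heel to toe.  In the foot frame +x always points from the medial to
the lateral side of the foot, which requires mirroring x for left feet.

The thirds and the axis are mutually dependent (the thirds are measured
along the axis, but H and T come from the thirds), so the estimate runs a
provisional principal-axis pass followed by one refinement pass along the
heel-to-toe line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mat_io import MatRecording, cell_center

__all__ = [
    "DegenerateFootfallError",
    "Footfall",
    "FootAxis",
    "detect_footfalls",
    "assign_sides",
    "estimate_axis",
    "transform_point",
    "transform_points",
]


class DegenerateFootfallError(ValueError):
    """Footfall too small or too collinear to carry a foot axis."""


@dataclass
class Footfall:
    """Cells of one foot contact with per-cell activation/deactivation times (ms)."""

    cells: dict[tuple[int, int], tuple[float, float]]
    index: int = 0
    side: str = "unknown"

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("footfall has no cells")
        for cell, (on, off) in self.cells.items():
            if off < on:
                raise ValueError(f"cell {cell}: deactivation before activation")

    @property
    def first_contact_ms(self) -> float:
        return min(on for on, _ in self.cells.values())

    @property
    def last_contact_ms(self) -> float:
        return max(off for _, off in self.cells.values())

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_centers(self, cell_pitch: float) -> np.ndarray:
        """(m, 2) array of physical (a, b) centers, in insertion order."""
        rc = np.array(sorted(self.cells), dtype=float)
        return np.column_stack(((rc[:, 1] + 0.5) * cell_pitch, (rc[:, 0] + 0.5) * cell_pitch))


@dataclass
class FootAxis:
    """Heel/toe pivot points and the mat-to-foot-frame rotation of one footfall."""

    heel: np.ndarray  # H = (e, f) mm, mat frame
    toe: np.ndarray  # T = (c, d) mm, mat frame
    theta_o: float  # inclination of the heel-to-toe line, atan2(d-f, c-e), rad
    theta_c: float  # signed angle from the mat's progression axis to the line, rad
    foot_length: float  # mm, extent along the line + one cell pitch
    foot_width: float  # mm, extent across the line + one cell pitch
    thirds: dict[str, frozenset[tuple[int, int]]] = field(default_factory=dict)

    @property
    def heel_toe_distance(self) -> float:
        return float(np.hypot(*(self.toe - self.heel)))


# ----------------------------------------------------------------------
# footfall detection


def _cell_intervals(rec: MatRecording, max_gap: int):
    """Split each cell's active frames into intervals bridging gaps <= max_gap."""
    per_cell: dict[tuple[int, int], list[int]] = {}
    for idx, cells in rec.frames:
        for r, c in cells[:, :2].astype(int):
            per_cell.setdefault((int(r), int(c)), []).append(idx)
    intervals = []  # (cell, first_frame, last_frame)
    for cell, frames in per_cell.items():
        start = prev = frames[0]
        for f in frames[1:]:
            if f - prev - 1 > max_gap:
                intervals.append((cell, start, prev))
                start = f
            prev = f
        intervals.append((cell, start, prev))
    return intervals


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def detect_footfalls(
    rec: MatRecording, min_cells: int = 5, max_gap: int = 2
) -> list[Footfall]:
    """Cluster active cells into footfalls.

    Two cell-activation intervals belong to the same footfall when their
    cells are identical or 8-adjacent and their time spans overlap or are
    separated by at most ``max_gap`` frames.  Clusters smaller than
    ``min_cells`` distinct cells are discarded.  Footfalls are returned in
    order of first contact, with ``index`` set 1-based.
    """
    intervals = _cell_intervals(rec, max_gap)
    if not intervals:
        return []
    by_cell: dict[tuple[int, int], list[int]] = {}
    for i, (cell, _, _) in enumerate(intervals):
        by_cell.setdefault(cell, []).append(i)

    uf = _UnionFind(len(intervals))
    for i, ((r, c), s1, e1) in enumerate(intervals):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for j in by_cell.get((r + dr, c + dc), ()):  # includes itself
                    if j <= i:
                        continue
                    s2, e2 = intervals[j][1], intervals[j][2]
                    if s2 <= e1 + max_gap + 1 and s1 <= e2 + max_gap + 1:
                        uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        clusters.setdefault(uf.find(i), []).append(i)

    footfalls = []
    for members in clusters.values():
        cells: dict[tuple[int, int], tuple[float, float]] = {}
        for i in members:
            cell, s, e = intervals[i]
            on, off = rec.frame_time_ms(s), rec.frame_time_ms(e)
            if cell in cells:
                on = min(on, cells[cell][0])
                off = max(off, cells[cell][1])
            cells[cell] = (float(on), float(off))
        if len(cells) >= min_cells:
            footfalls.append(Footfall(cells))
    footfalls.sort(key=lambda ff: (ff.first_contact_ms, min(ff.cells)))
    for i, ff in enumerate(footfalls, start=1):
        ff.index = i
    return footfalls


# ----------------------------------------------------------------------
# side assignment


def _progression_axes(walking_axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (along, lateral) of the walking direction in (a, b) mm space."""
    if walking_axis == "vertical":
        return np.array([0.0, 1.0]), np.array([1.0, 0.0])
    return np.array([1.0, 0.0]), np.array([0.0, 1.0])


def assign_sides(
    footfalls: list[Footfall], cell_pitch: float, walking_axis: str = "vertical"
) -> list[str]:
    """Label footfalls left/right from their lateral offset off the line of progression.

    Interior footfalls are sided by the sign of the cross product of the
    neighbour-to-neighbour progression vector with the footfall's offset
    from the neighbour midpoint; the first and last footfalls are filled in
    by alternation.  If the resulting sequence does not alternate the
    geometry is ambiguous and every footfall is labelled ``unknown``.
    Walking toward +along with standard axes, a positive lateral offset is
    the right foot.
    """
    n = len(footfalls)
    if n == 0:
        return []
    if n == 1:
        footfalls[0].side = "unknown"
        return ["unknown"]

    centroids = np.array(
        [ff.cell_centers(cell_pitch).mean(axis=0) for ff in footfalls]
    )
    along, _lateral = _progression_axes(walking_axis)

    def side_of(direction: np.ndarray, offset: np.ndarray) -> str:
        cross = direction[0] * offset[1] - direction[1] * offset[0]
        return "left" if cross > 0 else "right"

    sides: list[str | None] = [None] * n
    if n == 2:
        mid = centroids.mean(axis=0)
        for i in range(2):
            sides[i] = side_of(along, centroids[i] - mid)
    else:
        for i in range(1, n - 1):
            d = centroids[i + 1] - centroids[i - 1]
            ref = 0.5 * (centroids[i + 1] + centroids[i - 1])
            sides[i] = side_of(d, centroids[i] - ref)
        sides[0] = "left" if sides[1] == "right" else "right"
        sides[-1] = "left" if sides[-2] == "right" else "right"

    alternating = all(sides[i] != sides[i + 1] for i in range(n - 1))
    if not alternating:
        sides = ["unknown"] * n
    for ff, s in zip(footfalls, sides):
        ff.side = s
    return list(sides)  # type: ignore[arg-type]


# ----------------------------------------------------------------------
# axis estimation


def _split_thirds(
    cells: list[tuple[int, int]], centers: np.ndarray, direction: np.ndarray
) -> dict[str, frozenset[tuple[int, int]]]:
    """Partition cells into thirds of equal extent along ``direction``.

    Boundary ties go to the more proximal interval (<= on both cut points).
    """
    s = centers @ direction
    lo, hi = float(s.min()), float(s.max())
    length = hi - lo
    # ties go proximal; the small tolerance keeps boundary cells stable
    # under exact symmetries (e.g. a mirrored mat) despite fp rounding
    tol = 1e-9 * max(1.0, abs(lo), abs(hi))
    c1, c2 = lo + length / 3.0, lo + 2.0 * length / 3.0
    thirds: dict[str, set[tuple[int, int]]] = {"proximal": set(), "middle": set(), "distal": set()}
    for cell, si in zip(cells, s):
        if si <= c1 + tol:
            thirds["proximal"].add(cell)
        elif si <= c2 + tol:
            thirds["middle"].add(cell)
        else:
            thirds["distal"].add(cell)
    return {k: frozenset(v) for k, v in thirds.items()}


def estimate_axis(
    ff: Footfall, cell_pitch: float, walking_axis: str = "vertical"
) -> FootAxis:
    """Estimate heel/toe centers, theta_c and the thirds partition of a footfall.

    A provisional axis (principal component of the cell centers, oriented
    toward the walking direction) defines initial thirds; H and T are the
    centroids of the proximal and distal thirds; one refinement pass
    recomputes the thirds along the heel-to-toe line and re-derives H and T.
    """
    if ff.n_cells < 3:
        raise DegenerateFootfallError(
            f"footfall {ff.index}: need >= 3 cells, got {ff.n_cells}"
        )
    cells = sorted(ff.cells)
    centers = ff.cell_centers(cell_pitch)
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered / len(cells)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, int(np.argmax(evals))]
    along, _ = _progression_axes(walking_axis)
    if direction @ along < 0:
        direction = -direction
    if np.ptp(centers @ direction) == 0:
        raise DegenerateFootfallError(
            f"footfall {ff.index}: zero extent along provisional axis"
        )

    heel = toe = None
    thirds = _split_thirds(cells, centers, direction)
    for _pass in range(2):  # provisional pass + one refinement along l
        heel = _centroid(thirds["proximal"], cell_pitch)
        toe = _centroid(thirds["distal"], cell_pitch)
        line = toe - heel
        norm = float(np.hypot(*line))
        if norm == 0:
            raise DegenerateFootfallError(f"footfall {ff.index}: heel equals toe")
        direction = line / norm
        thirds = _split_thirds(cells, centers, direction)

    c, d = float(toe[0]), float(toe[1])
    e, f = float(heel[0]), float(heel[1])
    theta_o = math.atan2(d - f, c - e)
    theta_c = math.atan2(c - e, d - f)
    s = centers @ direction
    perp = np.array([-direction[1], direction[0]])
    w = centers @ perp
    return FootAxis(
        heel=heel,
        toe=toe,
        theta_o=theta_o,
        theta_c=theta_c,
        foot_length=float(np.ptp(s)) + cell_pitch,
        foot_width=float(np.ptp(w)) + cell_pitch,
        thirds=thirds,
    )


def _centroid(cells: frozenset[tuple[int, int]], cell_pitch: float) -> np.ndarray:
    pts = np.array([cell_center(r, c, cell_pitch) for r, c in sorted(cells)])
    return pts.mean(axis=0)


# ----------------------------------------------------------------------
# coordinate conversion


def transform_points(
    p_raw: np.ndarray, axis: FootAxis, side: str = "right"
) -> np.ndarray:
    """Rotate raw mat coordinates into the foot frame (origin H, +y heel-to-toe).

    Applies the rigid rotation by theta_c about the heel center.  For left
    feet x is negated afterwards so +x is medial-to-lateral on both sides.
    """
    p = np.atleast_2d(np.asarray(p_raw, dtype=float))
    ct, st = math.cos(axis.theta_c), math.sin(axis.theta_c)
    rot = np.array([[ct, -st], [st, ct]])
    out = (p - axis.heel) @ rot.T
    if side == "left":
        out = out.copy()
        out[:, 0] = -out[:, 0]
    return out


def transform_point(
    p_raw, axis: FootAxis, side: str = "right"
) -> tuple[float, float]:
    """Single-point convenience wrapper around :func:`transform_points`."""
    out = transform_points(np.asarray(p_raw, dtype=float).reshape(1, 2), axis, side)
    return float(out[0, 0]), float(out[0, 1])
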