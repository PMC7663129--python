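"""Arch index from a toe-excluded static footprint.

The arch index characterises the medial longitudinal arch: the toe-excluded
footprint is divided into three equal-length regions along its own long
axis, and the index is the middle-region contact area divided by the total
area, AI = b / (a + b + c) with a = distal, b = middle, c = proximal
region.  Flat feet load the midfoot and give large indices; high-arched
feet leave the midfoot unloaded and give small ones.  Classification cut
points are configurable; the defaults (AI < 0.21 high arch, AI > 0.26 low
arch) follow the common arch-index convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mat_io import FootprintGrid

__all__ = [
    "ArchIndexResult",
    "exclude_toes",
    "compute_arch_index",
    "classify_arch",
]


@dataclass(frozen=True)
class ArchIndexResult:
    """Region areas (cell counts), the arch index and its classification."""

    area_distal: int  # a
    area_middle: int  # b
    area_proximal: int  # c
    arch_index: float
    category: str

    @property
    def total_area(self) -> int:
        return self.area_distal + self.area_middle + self.area_proximal


def _label_components(fp: FootprintGrid):
    """8-connected components of the occupied cells, as a labelled dense grid."""
    rows = fp.cells[:, 0].astype(int)
    cols = fp.cells[:, 1].astype(int)
    r0, c0 = rows.min(), cols.min()
    grid = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    grid[rows - r0, cols - c0] = True
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    return labels, n, r0, c0


def exclude_toes(fp: FootprintGrid, distal: str = "increasing-row") -> FootprintGrid:
    """Remove toe cells from a footprint.

    With an explicit toe mask exactly those cells are removed.  Otherwise a
    geometric heuristic is used: the largest connected component is taken as
    the sole; among cross-section rows (perpendicular to the foot's long
    axis) that contain no cells at all, the most distal one marks the
    sole–toe gap, and every component lying entirely distal to it is
    removed.  A contiguous footprint with no distal gap is returned
    unchanged.  ``distal`` names the toe-ward direction along the grid rows
    (``"increasing-row"`` or ``"decreasing-row"``).

    Raises ``ValueError`` when the heuristic would remove more than 40% of
    the footprint area, which indicates the toes are not separable and an
    explicit mask is needed.
    """
    if fp.toe_mask is not None:
        return fp.without_cells(set(fp.toe_mask))
    if distal not in ("increasing-row", "decreasing-row"):
        raise ValueError(f"bad distal direction {distal!r}")

    labels, n, r0, c0 = _label_components(fp)
    if n <= 1:
        return fp
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    main = int(np.argmax(sizes)) + 1

    occupied_rows = labels.any(axis=1)
    empty_rows = np.flatnonzero(~occupied_rows)
    if empty_rows.size == 0:
        return fp
    if distal == "increasing-row":
        gap_row = empty_rows.max()
    else:
        gap_row = empty_rows.min()

    drop_labels = set()
    for lab in range(1, n + 1):
        if lab == main:
            continue
        rr = np.nonzero(labels == lab)[0]
        if distal == "increasing-row" and rr.min() > gap_row:
            drop_labels.add(lab)
        elif distal == "decreasing-row" and rr.max() < gap_row:
            drop_labels.add(lab)
    if not drop_labels:
        return fp

    drop_cells = set()
    for r, c, _p in fp.cells:
        lab = labels[int(r) - r0, int(c) - c0]
        if lab in drop_labels:
            drop_cells.add((int(r), int(c)))
    removed_frac = len(drop_cells) / fp.cells.shape[0]
    if removed_frac > 0.40:
        raise ValueError(
            f"toe heuristic would remove {removed_frac:.0%} of the footprint; "
            "provide an explicit toe mask"
        )
    return fp.without_cells(drop_cells)


def compute_arch_index(
    fp: FootprintGrid, distal: str = "increasing-row"
) -> ArchIndexResult:
    """Arch index of a toe-excluded footprint.

    The footprint's own length is measured along its principal axis (so the
    result is invariant to footprint rotation up to cell discretisation),
    split into three equal intervals, and the occupied area of each interval
    counted.  Cells whose center falls exactly on a cut point go to the more
    proximal interval.
    """
    pts = np.column_stack(
        ((fp.cells[:, 1] + 0.5) * fp.cell_pitch, (fp.cells[:, 0] + 0.5) * fp.cell_pitch)
    )
    if pts.shape[0] == 0:
        raise ValueError("empty footprint")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, int(np.argmax(evals))]
    # orient toward the toes so 'distal' is well defined; b grows with row
    toe_ward = np.array([0.0, 1.0]) if distal == "increasing-row" else np.array([0.0, -1.0])
    if direction @ toe_ward < 0:
        direction = -direction

    s = pts @ direction
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        raise ValueError("footprint has zero extent along its axis")
    c1, c2 = lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0
    proximal = int((s <= c1).sum())
    middle = int(((s > c1) & (s <= c2)).sum())
    distal_area = int((s > c2).sum())
    ai = middle / pts.shape[0]
    return ArchIndexResult(
        area_distal=distal_area,
        area_middle=middle,
        area_proximal=proximal,
        arch_index=ai,
        category=classify_arch(ai),
    )


def classify_arch(
    arch_index: float, thresholds: tuple[float, float] = (0.21, 0.26)
) -> str:
    """Classify an arch index as ``"high"``, ``"normal"`` or ``"low"`` arch.

    A small index means little midfoot contact, i.e. a *high* medial arch.
    """
    low_cut, high_cut = thresholds
    if low_cut > high_cut:
        raise ValueError("thresholds must be (low_cut <= high_cut)")
    if not 0.0 <= arch_index <= 1.0:
        raise ValueError(f"arch index must be in [0, 1], got {arch_index}")
    if arch_index < low_cut:
        return "high"
    if arch_index > high_cut:
        return "low"
    return "normal"
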