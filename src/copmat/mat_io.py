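"""Plain-text interchange I/O for pressure-mat recordings and footprints.

The on-disk recording format is a long-form CSV with a ``#key=value`` header
block::

    #sampling_rate=240.0
    #cell_pitch_mm=12.7
    #grid_rows=288
    #grid_cols=48
    #walking_axis=vertical
    frame,row,col,pressure
    0,12,31,0.42
    ...

Cell indices are 0-based.  Physical coordinates are cell centers: cell
(row, col) sits at ``a = (col + 0.5) * pitch`` mm on the horizontal mat axis
and ``b = (row + 0.5) * pitch`` mm on the vertical (long) axis.  The long
axis is the default direction of progression; recordings captured walking
the other way set ``walking_axis=horizontal``.

Static footprints (for the arch index) use the same convention with rows
``row,col,pressure[,is_toe]`` and an optional per-cell toe flag.

Pressure may be graded or binary (binary devices write 1.0); the pipeline
never assumes calibrated units, only non-negativity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MatFormatError",
    "MatRecording",
    "FootprintGrid",
    "cell_center",
    "read_recording",
    "write_recording",
    "read_footprint",
    "write_footprint",
]


class MatFormatError(ValueError):
    """Raised for malformed or invalid interchange files."""


def cell_center(row: int, col: int, cell_pitch: float) -> tuple[float, float]:
    """Physical center ``(a, b)`` in mm of a grid cell.

    ``a`` runs along the horizontal mat axis (columns), ``b`` along the
    vertical/long axis (rows); the half-cell offset places coordinates at
    cell centers rather than corners.
    """
    return ((col + 0.5) * cell_pitch, (row + 0.5) * cell_pitch)


@dataclass
class MatRecording:
    """A time-ordered sequence of active-cell frames on a fixed grid.

    ``frames`` is a list of ``(frame_index, cells)`` pairs with strictly
    increasing frame indices; ``cells`` is a float array of shape (m, 3)
    holding ``row, col, pressure`` per active cell.  Frames with no active
    cells may be present as empty arrays.
    """

    grid_rows: int
    grid_cols: int
    frames: list[tuple[int, np.ndarray]] = field(default_factory=list)
    sampling_rate: float = 240.0
    cell_pitch: float = 12.7
    walking_axis: str = "vertical"

    def __post_init__(self) -> None:
        self.validate()

    # -- helpers -------------------------------------------------------
    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def frame_time_ms(self, frame_index: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(frame_index, dtype=float) * self.frame_period_ms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise MatFormatError("sampling_rate must be positive")
        if self.cell_pitch <= 0:
            raise MatFormatError("cell_pitch must be positive")
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise MatFormatError("grid dimensions must be positive")
        if self.walking_axis not in ("vertical", "horizontal"):
            raise MatFormatError(
                f"walking_axis must be 'vertical' or 'horizontal', got {self.walking_axis!r}"
            )
        last = None
        norm_frames: list[tuple[int, np.ndarray]] = []
        for idx, cells in self.frames:
            idx = int(idx)
            if last is not None and idx <= last:
                raise MatFormatError(f"frame indices not strictly increasing at frame {idx}")
            last = idx
            arr = np.asarray(cells, dtype=float).reshape(-1, 3)
            if arr.size:
                rows, cols, press = arr[:, 0], arr[:, 1], arr[:, 2]
                if (rows < 0).any() or (rows >= self.grid_rows).any() or (
                    cols < 0
                ).any() or (cols >= self.grid_cols).any():
                    raise MatFormatError(f"cell out of grid bounds in frame {idx}")
                if (press < 0).any():
                    raise MatFormatError(f"negative pressure in frame {idx}")
            norm_frames.append((idx, arr))
        self.frames = norm_frames

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, MatRecording):
            return NotImplemented
        if (
            self.grid_rows != other.grid_rows
            or self.grid_cols != other.grid_cols
            or self.sampling_rate != other.sampling_rate
            or self.cell_pitch != other.cell_pitch
            or self.walking_axis != other.walking_axis
            or len(self.frames) != len(other.frames)
        ):
            return False
        for (i1, c1), (i2, c2) in zip(self.frames, other.frames):
            if i1 != i2 or c1.shape != c2.shape or not np.array_equal(c1, c2):
                return False
        return True


@dataclass
class FootprintGrid:
    """A static footprint: occupied cells with pressure, plus an optional toe mask."""

    cells: np.ndarray  # (m, 3) row, col, pressure
    cell_pitch: float = 12.7
    toe_mask: frozenset[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float).reshape(-1, 3)
        if self.cells.shape[0] == 0:
            raise MatFormatError("footprint is empty")
        if self.cell_pitch <= 0:
            raise MatFormatError("cell_pitch must be positive")
        if (self.cells[:, 2] < 0).any():
            raise MatFormatError("negative pressure in footprint")
        occupied = self.cell_set()
        if self.toe_mask is not None:
            self.toe_mask = frozenset((int(r), int(c)) for r, c in self.toe_mask)
            if not self.toe_mask <= occupied:
                raise MatFormatError("toe mask contains cells not in the footprint")

    def cell_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((int(r), int(c)) for r, c in self.cells[:, :2])

    def without_cells(self, drop: set[tuple[int, int]]) -> "FootprintGrid":
        keep = np.array(
            [(int(r), int(c)) not in drop for r, c in self.cells[:, :2]], dtype=bool
        )
        mask = None
        if self.toe_mask is not None:
            mask = frozenset(c for c in self.toe_mask if c not in drop)
            mask = mask or None
        return FootprintGrid(self.cells[keep], self.cell_pitch, mask)


# ----------------------------------------------------------------------
# recording I/O

_REC_HEADER_KEYS = {
    "sampling_rate": float,
    "cell_pitch_mm": float,
    "grid_rows": int,
    "grid_cols": int,
    "walking_axis": str,
}


def _parse_header(lines: list[str], allowed: dict) -> tuple[dict, int]:
    meta: dict = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" not in body:
            raise MatFormatError(f"line {i + 1}: malformed header line {line!r}")
        key, _, value = body.partition("=")
        key = key.strip()
        if key not in allowed:
            raise MatFormatError(f"line {i + 1}: unknown header key {key!r}")
        try:
            meta[key] = allowed[key](value.strip())
        except ValueError as exc:
            raise MatFormatError(f"line {i + 1}: bad header value {value!r}") from exc
    else:
        i = len(lines)
    return meta, i


def read_recording(path, **overrides) -> MatRecording:
    """Read a recording CSV; keyword ``overrides`` replace header metadata.

    Raises :class:`MatFormatError` naming the offending line for malformed
    rows, out-of-bounds cells or non-monotone frame indices.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    meta, start = _parse_header(lines, _REC_HEADER_KEYS)
    meta = {
        "sampling_rate": meta.get("sampling_rate", 240.0),
        "cell_pitch": meta.get("cell_pitch_mm", 12.7),
        "grid_rows": meta.get("grid_rows"),
        "grid_cols": meta.get("grid_cols"),
        "walking_axis": meta.get("walking_axis", "vertical"),
    }
    meta.update(overrides)
    if meta["grid_rows"] is None or meta["grid_cols"] is None:
        raise MatFormatError("header must declare grid_rows and grid_cols")

    if start < len(lines):
        cols = [c.strip() for c in lines[start].split(",")]
        if cols != ["frame", "row", "col", "pressure"]:
            raise MatFormatError(f"line {start + 1}: expected column header 'frame,row,col,pressure'")
        start += 1

    frames: dict[int, list[tuple[float, float, float]]] = {}
    order: list[int] = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise MatFormatError(f"line {ln}: expected 4 fields, got {len(parts)}")
        try:
            f = int(parts[0])
            empty = parts[1] == "" and parts[2] == "" and parts[3] == ""
            if not empty:
                r, c, p = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise MatFormatError(f"line {ln}: malformed row {line!r}") from exc
        if f not in frames:
            if order and f < order[-1]:
                raise MatFormatError(f"line {ln}: frame index {f} not monotone")
            frames[f] = []
            order.append(f)
        if not empty:
            frames[f].append((r, c, p))

    frame_list = [
        (f, np.array(frames[f], dtype=float) if frames[f] else np.empty((0, 3)))
        for f in order
    ]
    return MatRecording(
        grid_rows=int(meta["grid_rows"]),
        grid_cols=int(meta["grid_cols"]),
        frames=frame_list,
        sampling_rate=float(meta["sampling_rate"]),
        cell_pitch=float(meta["cell_pitch"]),
        walking_axis=meta["walking_axis"],
    )


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest representation that round-trips exactly


def write_recording(rec: MatRecording, path) -> None:
    """Write ``rec`` so that :func:`read_recording` reproduces it exactly."""
    rec.validate()
    buf = io.StringIO()
    buf.write(f"#sampling_rate={_fmt(rec.sampling_rate)}\n")
    buf.write(f"#cell_pitch_mm={_fmt(rec.cell_pitch)}\n")
    buf.write(f"#grid_rows={rec.grid_rows}\n")
    buf.write(f"#grid_cols={rec.grid_cols}\n")
    buf.write(f"#walking_axis={rec.walking_axis}\n")
    buf.write("frame,row,col,pressure\n")
    for idx, cells in rec.frames:
        if cells.shape[0] == 0:
            buf.write(f"{idx},,,\n")  # frame present but no active cells
        for r, c, p in cells:
            buf.write(f"{idx},{int(r)},{int(c)},{_fmt(p)}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ----------------------------------------------------------------------
# footprint I/O

_FP_HEADER_KEYS = {"cell_pitch_mm": float}


def read_footprint(path, **overrides) -> FootprintGrid:
    """Read a footprint CSV (``row,col,pressure[,is_toe]``)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    meta, start = _parse_header(lines, _FP_HEADER_KEYS)
    pitch = overrides.get("cell_pitch", meta.get("cell_pitch_mm", 12.7))
    has_toe = False
    if start < len(lines):
        cols = [c.strip() for c in lines[start].split(",")]
        if cols == ["row", "col", "pressure", "is_toe"]:
            has_toe = True
        elif cols != ["row", "col", "pressure"]:
            raise MatFormatError(f"line {start + 1}: bad footprint column header")
        start += 1
    cells: list[tuple[float, float, float]] = []
    toe: set[tuple[int, int]] = set()
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) not in (3, 4):
            raise MatFormatError(f"line {ln}: expected 3 or 4 fields")
        try:
            r, c, p = int(parts[0]), int(parts[1]), float(parts[2])
            flag = int(parts[3]) if len(parts) == 4 else 0
        except ValueError as exc:
            raise MatFormatError(f"line {ln}: malformed row {line!r}") from exc
        cells.append((r, c, p))
        if flag:
            toe.add((r, c))
    return FootprintGrid(
        np.array(cells, dtype=float).reshape(-1, 3),
        cell_pitch=float(pitch),
        toe_mask=frozenset(toe) if (has_toe and toe) else None,
    )


def write_footprint(fp: FootprintGrid, path) -> None:
    toe = fp.toe_mask or frozenset()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#cell_pitch_mm={_fmt(fp.cell_pitch)}\n")
        if toe:
            fh.write("row,col,pressure,is_toe\n")
            for r, c, p in fp.cells:
                fh.write(f"{int(r)},{int(c)},{_fmt(p)},{int((int(r), int(c)) in toe)}\n")
        else:
            fh.write("row,col,pressure\n")
            for r, c, p in fp.cells:
                fh.write(f"{int(r)},{int(c)},{_fmt(p)}\n")


def with_metadata(rec: MatRecording, **kwargs) -> MatRecording:
    """Copy ``rec`` with replaced metadata fields."""
    return replace(rec, **kwargs)
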