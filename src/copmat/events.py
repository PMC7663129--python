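"""Stance-phase event detection and subphase bookkeeping.

Six time points partition the stance phase of one footfall:

* FCT — first contact: earliest activation of any cell.
* MON — midfoot-on: earliest activation in the middle third.
* FFT — foot-flat: the instant when 78% of the footfall's sensors have been
  activated (cumulative distinct-cell count, threshold ``ceil(0.78 * N)``).
* HOT — heel-off: last deactivation in the proximal third.
* MOF — midfoot-off: last deactivation in the middle third.
* LCT — last contact: latest deactivation of any cell.

Between them lie the subphases ICP (FCT–MON), LCP (MON–FFT), FFP (FFT–HOT),
IPP (HOT–MOF) and LPP (MOF–LCT); CbP combines LCP and FFP (MON–FFT–HOT
collapsed to MON–HOT).  All temporal quantities are normalised by stance
duration and expressed as percentages, so FCT is 0% and LCT is 100%.

Events are taken at the device's frame resolution — cells switch on/off at
frame times, and no sub-frame interpolation is attempted.  Footfalls whose
events come out non-monotone (possible with erratic contacts) are flagged
invalid rather than clamped, mirroring the practice of discarding trials
with unusual motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import FootAxis, Footfall

__all__ = [
    "StanceEvents",
    "SubphaseSet",
    "EVENT_NAMES",
    "SUBPHASE_BOUNDS",
    "detect_events",
    "normalize_events",
    "build_subphases",
]

EVENT_NAMES = ("FCT", "MON", "FFT", "HOT", "MOF", "LCT")

#: subphase -> (start event, end event)
SUBPHASE_BOUNDS = {
    "ICP": ("FCT", "MON"),
    "LCP": ("MON", "FFT"),
    "FFP": ("FFT", "HOT"),
    "CbP": ("MON", "HOT"),
    "IPP": ("HOT", "MOF"),
    "LPP": ("MOF", "LCT"),
}

#: the five exhaustive subphases (CbP overlaps LCP+FFP and is excluded)
PRIMARY_SUBPHASES = ("ICP", "LCP", "FFP", "IPP", "LPP")


@dataclass(frozen=True)
class StanceEvents:
    """The six stance-phase time points of one footfall, in ms."""

    fct_ms: float
    mon_ms: float
    fft_ms: float
    hot_ms: float
    mof_ms: float
    lct_ms: float
    valid: bool = True
    reason: str | None = None

    @property
    def stance_ms(self) -> float:
        return self.lct_ms - self.fct_ms

    def time_ms(self, name: str) -> float:
        return getattr(self, f"{name.lower()}_ms")

    def as_dict(self) -> dict[str, float]:
        return {name: self.time_ms(name) for name in EVENT_NAMES}


def detect_events(
    ff: Footfall, axis: FootAxis, fft_rule: str = "cumulative"
) -> StanceEvents:
    """Detect the six stance events of a footfall from per-cell on/off times.

    ``fft_rule`` selects how the 78% foot-flat criterion counts sensors:
    ``"cumulative"`` (default) counts distinct cells ever activated;
    ``"concurrent"`` counts cells simultaneously active.  The threshold is
    ``ceil(0.78 * N)`` cells in either case.

    Raises ``ValueError`` if a third of the footfall holds no cells; a
    non-monotone event sequence yields ``valid=False`` with a reason instead
    of an exception so callers can exclude and log the footfall.
    """
    for name in ("proximal", "middle", "distal"):
        if not axis.thirds.get(name):
            raise ValueError(f"footfall {ff.index}: empty {name} third")

    ons = {cell: t[0] for cell, t in ff.cells.items()}
    offs = {cell: t[1] for cell, t in ff.cells.items()}
    fct = min(ons.values())
    lct = max(offs.values())
    mon = min(ons[c] for c in axis.thirds["middle"])
    hot = max(offs[c] for c in axis.thirds["proximal"])
    mof = max(offs[c] for c in axis.thirds["middle"])

    n = ff.n_cells
    threshold = math.ceil(0.78 * n)
    if fft_rule == "cumulative":
        fft = sorted(ons.values())[threshold - 1]
    elif fft_rule == "concurrent":
        fft = _concurrent_threshold_time(ff, threshold)
    else:
        raise ValueError(f"unknown fft_rule {fft_rule!r}")

    events = StanceEvents(fct, mon, fft, hot, mof, lct)
    order = [events.time_ms(name) for name in EVENT_NAMES]
    if any(b < a for a, b in zip(order, order[1:])):
        bad = next(
            f"{EVENT_NAMES[i + 1]} < {EVENT_NAMES[i]}"
            for i in range(5)
            if order[i + 1] < order[i]
        )
        return StanceEvents(fct, mon, fft, hot, mof, lct, valid=False, reason=bad)
    return events


def _concurrent_threshold_time(ff: Footfall, threshold: int) -> float:
    """Earliest time at which >= threshold cells are simultaneously active."""
    changes: list[tuple[float, int]] = []
    for on, off in ff.cells.values():
        changes.append((on, +1))
        changes.append((off, -1))
    # at equal times, activations are processed before deactivations
    changes.sort(key=lambda t: (t[0], -t[1]))
    count = 0
    best = None
    for t, delta in changes:
        count += delta
        if count >= threshold:
            best = t
            break
    if best is None:
        raise ValueError(
            f"footfall {ff.index}: concurrent activation never reaches {threshold} cells"
        )
    return best


def normalize_events(ev: StanceEvents) -> dict[str, float]:
    """Express each event as a percentage of stance duration (FCT=0, LCT=100)."""
    if ev.stance_ms <= 0:
        raise ValueError("zero or negative stance duration")
    return {
        name: 100.0 * (ev.time_ms(name) - ev.fct_ms) / ev.stance_ms
        for name in EVENT_NAMES
    }


@dataclass(frozen=True)
class SubphaseSet:
    """Subphase intervals (ms) and their durations as % of stance."""

    intervals_ms: dict[str, tuple[float, float]]
    duration_pct: dict[str, float]

    def interval(self, name: str) -> tuple[float, float]:
        return self.intervals_ms[name]


def build_subphases(ev: StanceEvents) -> SubphaseSet:
    """Build the subphase intervals of a valid, monotone event set.

    The five exhaustive subphases tile the stance exactly, so their
    percentage durations sum to 100; CbP equals LCP + FFP by construction.
    """
    order = [ev.time_ms(name) for name in EVENT_NAMES]
    if any(b < a for a, b in zip(order, order[1:])):
        raise ValueError("non-monotone stance events")
    if ev.stance_ms <= 0:
        raise ValueError("zero stance duration")
    pct = normalize_events(ev)
    intervals = {
        name: (ev.time_ms(a), ev.time_ms(b)) for name, (a, b) in SUBPHASE_BOUNDS.items()
    }
    durations = {name: pct[b] - pct[a] for name, (a, b) in SUBPHASE_BOUNDS.items()}
    return SubphaseSet(intervals_ms=intervals, duration_pct=durations)
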