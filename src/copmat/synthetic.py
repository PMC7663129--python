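"""Synthetic pressure-mat walking trials with exact ground truth.

The generator emulates heel-to-toe rollover on a walkway mat so the whole
pipeline — footfall detection, axis estimation, event detection and COP
parameterisation — can be exercised and checked without hardware.

Model.  Each footfall is a foot-shaped template of grid cells (rounded
heel, medially waisted midfoot, wide forefoot).  A cell's activation time
grows with its position ``u`` along the foot axis (a heel-to-toe contact
wave), its deactivation likewise; both are piecewise-linear in ``u`` with
knots placed at the configured event-time fractions, so contact begins at
the heel, the forefoot loads progressively, and the heel releases first.
Per-cell pressure follows a smooth half-sine rise-and-fall between the
cell's on and off times, with a mediolateral amplitude bias that moves the
COP medially at the ends of stance and laterally in midstance.  Because the
per-cell on/off times and pressure profiles are known in continuous time,
every quantity the pipeline estimates (events, axis, trajectory,
parameters) has an exactly computable ground-truth counterpart.

Variability.  Subject-level traits (foot size, stance duration, event
fractions, toe-out angle, walking speed) are drawn from between-subject
distributions; footfall-level jitter adds the within-subject component.
The defaults reproduce the scale of a healthy young adult cohort walking
at a comfortable pace (foot 240 x 100 mm, stance about 614 ms, event
targets near 8.8 / 40.9 / 59.3 / 87.0 % of stance).  No claim of
physiological fidelity beyond those scales is made.

Parameter matrices for the reliability statistics are generated directly
from the one-way variance-components model value(i,j) = mu + b_i + e_ij,
whose true ICC is sigma_b^2 / (sigma_b^2 + sigma_w^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import StanceEvents, detect_events
from .geometry import FootAxis, Footfall, estimate_axis, transform_points
from .mat_io import FootprintGrid, MatRecording
from .parameters import CopTrajectory, subphase_parameters

__all__ = [
    "SynthConfig",
    "SubjectTraits",
    "TrueFootfall",
    "GroundTruth",
    "draw_subject",
    "generate_footfall",
    "generate_recording",
    "generate_cohort",
    "generate_parameter_matrix",
    "generate_footprint",
]


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic walking cohort.

    Between/within pairs are SDs of the subject-level draw and of the
    per-footfall jitter.  Event fractions are % of stance / 100.
    """

    seed: int = 0
    n_subjects: int = 10
    n_steps: int = 16  # footfalls per recording (both feet)

    # mat geometry / device
    sampling_rate: float = 240.0
    cell_pitch_mm: float = 12.7
    grid_cols: int = 48
    grid_rows: int | None = None  # None: auto-size to the walk

    # gait scale
    speed_cmps: tuple[float, float] = (129.0, 16.0)  # mean, between-SD
    cadence_spm: float = 118.3
    stance_ms: tuple[float, float, float] = (613.7, 45.0, 17.0)  # mean, between, within
    step_width_mm: tuple[float, float] = (90.0, 8.0)  # mean, within jitter
    foot_length_mm: tuple[float, float] = (240.1, 17.3)
    foot_width_mm: tuple[float, float] = (100.1, 9.9)
    toe_out_deg: tuple[float, float, float] = (5.0, 3.0, 2.0)  # mean, between, within

    # contact-wave event targets (fraction of stance): MON, FFT, HOT, MOF
    event_fractions: tuple[float, float, float, float] = (0.0883, 0.4085, 0.5932, 0.8702)
    event_between_sd: tuple[float, float, float, float] = (0.021, 0.055, 0.045, 0.030)
    event_within_sd: tuple[float, float, float, float] = (0.011, 0.045, 0.035, 0.030)

    # footprint shape
    arch_depth: float = 0.6  # medial waist depth as a fraction of the half width
    ml_pressure_gain: float = 0.25  # static (per-cell) mediolateral bias
    ml_time_gain: float = 0.35  # time-varying mediolateral sweep strength
    sensor_threshold: float = 0.15  # minimum reported load (fraction of nominal)

    # noise
    timing_jitter_ms: float = 0.0  # per-cell Gaussian jitter on on/off times
    noise_rate: float = 0.0  # spurious flicker cells per footfall cell

    def validate(self) -> None:
        fr = self.event_fractions
        if not (0.0 < fr[0] < fr[1] < fr[2] < fr[3] < 1.0):
            raise ValueError("event fractions must be ordered in (0, 1)")
        if self.n_steps < 1 or self.n_subjects < 1:
            raise ValueError("n_steps and n_subjects must be positive")
        for sd in (*self.event_between_sd, *self.event_within_sd,
                   self.stance_ms[1], self.stance_ms[2], self.timing_jitter_ms):
            if sd < 0:
                raise ValueError("SDs must be non-negative")


@dataclass
class SubjectTraits:
    """Subject-level draw: everything constant across one subject's footfalls."""

    foot_length: float
    foot_width: float
    stance_ms: float
    fractions: tuple[float, float, float, float]
    toe_out_deg: float
    speed_cmps: float
    step_time_ms: float
    step_length_mm: float


def draw_subject(cfg: SynthConfig, rng: np.random.Generator) -> SubjectTraits:
    cfg.validate()
    fl = max(150.0, rng.normal(*cfg.foot_length_mm))
    fw = max(60.0, rng.normal(*cfg.foot_width_mm))
    stance = max(300.0, rng.normal(cfg.stance_ms[0], cfg.stance_ms[1]))
    fr = _clamp_fractions(
        np.array(cfg.event_fractions) + rng.normal(0.0, cfg.event_between_sd)
    )
    speed = max(60.0, rng.normal(*cfg.speed_cmps))
    step_time = 60_000.0 / cfg.cadence_spm  # ms per step
    step_len = speed * 10.0 * step_time / 1000.0  # cm/s -> mm over one step
    return SubjectTraits(
        foot_length=fl,
        foot_width=fw,
        stance_ms=stance,
        fractions=tuple(fr),
        toe_out_deg=rng.normal(cfg.toe_out_deg[0], cfg.toe_out_deg[1]),
        speed_cmps=speed,
        step_time_ms=step_time,
        step_length_mm=step_len,
    )


def _clamp_fractions(fr: np.ndarray) -> np.ndarray:
    """Force MON < FFT < HOT < MOF with margins, inside (0, 0.97)."""
    mon = float(np.clip(fr[0], 0.02, 0.30))
    fft = float(np.clip(fr[1], mon + 0.03, 0.70))
    hot = float(np.clip(fr[2], fft + 0.03, 0.85))
    mof = float(np.clip(fr[3], hot + 0.05, 0.97))
    return np.array([mon, fft, hot, mof])


# ----------------------------------------------------------------------
# single footfall


@dataclass
class TrueFootfall:
    """Ground truth for one generated footfall, at generator resolution.

    The event times and the foot axis follow the detector's own rules —
    thirds along the refined heel-to-toe axis, 78% cumulative activation —
    evaluated on the continuous planted cell times, so any discrepancy with
    the pipeline is pure device discretisation.  ``theta_placed`` keeps the
    planted placement angle, which the axis estimate should recover only
    approximately (the template is not symmetric about its midline).
    """

    index: int
    side: str
    cells: dict[tuple[int, int], tuple[float, float, float, float]]  # (r,c) -> on, off, amp, vhat
    heel: np.ndarray  # H, mm mat frame
    toe: np.ndarray  # T
    theta_c: float
    theta_placed: float  # planted toe-out angle, rad, signed like theta_c
    foot_length: float  # extent along the axis + one pitch
    foot_width: float
    events: StanceEvents  # continuous-time events from the planted cell times
    cell_pitch: float
    t0_ms: float = 0.0  # planted stance start (for the ML sweep phase)
    stance_dur_ms: float = 1.0
    ml_time_gain: float = 0.0
    sensor_threshold: float = 0.15
    thirds: dict[str, frozenset[tuple[int, int]]] = field(default_factory=dict)

    @property
    def cell_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.cells)

    def axis(self) -> FootAxis:
        return FootAxis(
            heel=self.heel,
            toe=self.toe,
            theta_o=math.atan2(
                self.toe[1] - self.heel[1], self.toe[0] - self.heel[0]
            ),
            theta_c=self.theta_c,
            foot_length=self.foot_length,
            foot_width=self.foot_width,
            thirds=self.thirds,
        )

    def trajectory(self, oversample: int = 4, sampling_rate: float = 240.0) -> CopTrajectory:
        """Continuous-model COP trajectory sampled at oversample x device rate.

        Samples sit on the device clock grid (subdivided ``oversample``
        times), not on the footfall's own onset: a clocked mat never
        observes the exact first-contact instant, and the COP there — a
        single barely loaded cell — is not part of what the method
        measures.
        """
        step = 1000.0 / (sampling_rate * oversample)
        k0 = int(math.ceil(self.events.fct_ms / step - 1e-6))
        k1 = int(math.floor(self.events.lct_ms / step + 1e-6))
        times = np.arange(k0, k1 + 1) * step
        rc = np.array(sorted(self.cells), dtype=float)
        vals = np.array([self.cells[(int(r), int(c))] for r, c in rc])
        ons, offs, amps, vhats = vals.T
        centers = np.column_stack(
            ((rc[:, 1] + 0.5) * self.cell_pitch, (rc[:, 0] + 0.5) * self.cell_pitch)
        )
        raw, kept = [], []
        for t in times:
            p = _pressure_profile(
                t, ons, offs, amps, vhats,
                self.t0_ms, self.stance_dur_ms, self.ml_time_gain,
                self.sensor_threshold,
            )
            total = p.sum()
            if total <= 0:
                continue
            raw.append((centers * p[:, None]).sum(axis=0) / total)
            kept.append(t)
        raw = np.array(raw)
        foot = transform_points(raw, self.axis(), self.side)
        return CopTrajectory(
            np.array(kept), raw, foot, footfall_index=self.index, side=self.side
        )

    def parameters(self, oversample: int = 1, sampling_rate: float = 240.0) -> dict:
        """Ground-truth parameter set from the continuous COP model.

        Evaluated by default on the device time base (``oversample=1``):
        the method's displacement and path-length parameters are defined on
        the sampled COP sequence, so that is the estimand the pipeline
        should recover — a continuous path length is strictly larger than
        any sampled one and is not what a mat can measure.  Pass a larger
        ``oversample`` to probe the continuous model instead.
        """
        traj = self.trajectory(oversample=oversample, sampling_rate=sampling_rate)
        return subphase_parameters(traj, self.events, self.foot_length, self.foot_width)


_RISE_MS = 50.0  # upper bound on a cell's load rise time


def _pressure_profile(t, ons, offs, amps, vhats, t0, stance_dur, ml_gain,
                      threshold=0.15):
    """Per-cell reported pressure at time t (vectorised over cells).

    Each cell loads quickly — a quarter-sine rise over at most 50 ms (heel
    strike and forefoot loading are much faster than the stance) — and
    unloads with a quarter-cosine over the rest of its active span.  Mat
    sensors switch on at a load threshold, so the reported pressure jumps
    from zero to ``threshold`` at activation and never hovers near zero
    (a COP at vanishing total load would be numerically meaningless).  The
    result is multiplied by a slow mediolateral weight sweep
    -cos(2*pi*tau) over the stance (tau in [0, 1]): pressure is biased
    medially at the ends of stance and laterally in midstance, which drags
    the COP smoothly across the foot at timescales a 240 Hz device
    resolves.
    """
    dur = np.maximum(offs - ons, 1e-9)
    rise = np.minimum(_RISE_MS, 0.4 * dur)
    dt = t - ons
    active = (dt >= -1e-6) & (dt <= dur + 1e-6)  # tolerate clock-time rounding
    rising = dt < rise
    fall_phase = np.clip((dt - rise) / np.maximum(dur - rise, 1e-9), 0.0, 1.0)
    shape = np.where(
        rising,
        np.sin(0.5 * np.pi * np.clip(dt / rise, 0.0, 1.0)),
        np.cos(0.5 * np.pi * fall_phase),
    )
    base = threshold + (1.0 - threshold) * shape
    tau = np.clip((t - t0) / max(stance_dur, 1e-9), 0.0, 1.0)
    sweep = np.maximum(1.0 - ml_gain * np.cos(2.0 * np.pi * tau) * vhats, 0.05)
    return np.where(active, amps * base * sweep, 0.0)


def _half_width(u: np.ndarray, fw: float) -> np.ndarray:
    """Half-width profile of the foot outline at along-position u.

    Widest at the metatarsal heads (u ~ 0.75), waisted at the midfoot,
    rounded heel and toes.
    """
    u = np.asarray(u, dtype=float)
    shape = (
        0.72
        + 0.28 * np.exp(-(((u - 0.75) / 0.16) ** 2))
        - 0.18 * np.exp(-(((u - 0.42) / 0.15) ** 2))
    )
    return 0.5 * fw * np.clip(shape, 0.30, 1.0)


def generate_footfall(
    cfg: SynthConfig,
    traits: SubjectTraits,
    rng: np.random.Generator,
    heel_pos: tuple[float, float],
    side: str,
    t0_ms: float,
    index: int = 0,
    grid_rows: int | None = None,
) -> TrueFootfall:
    """Plant one rollover footfall on the mat and return its ground truth.

    ``heel_pos`` is the physical (a, b) position of the heel tip in mm.
    Raises ``ValueError`` if the template does not fit on the grid.
    """
    pitch = cfg.cell_pitch_mm
    fl, fw = traits.foot_length, traits.foot_width
    stance = max(200.0, traits.stance_ms + rng.normal(0.0, cfg.stance_ms[2]))
    fr = _clamp_fractions(
        np.array(traits.fractions) + rng.normal(0.0, cfg.event_within_sd)
    )
    mon_f, fft_f, hot_f, mof_f = fr
    sign = 1.0 if side == "right" else -1.0
    theta = math.radians(
        sign * abs(traits.toe_out_deg + rng.normal(0.0, cfg.toe_out_deg[2]))
    )

    origin = np.array(heel_pos, dtype=float)
    direction = np.array([math.sin(theta), math.cos(theta)])
    right_perp = np.array([math.cos(theta), -math.sin(theta)])
    lateral = right_perp if side == "right" else -right_perp

    # candidate cells from the bounding box of the outline
    corners = [
        origin - lateral * fw,
        origin + lateral * fw,
        origin + direction * fl - lateral * fw,
        origin + direction * fl + lateral * fw,
    ]
    amin = min(p[0] for p in corners)
    amax = max(p[0] for p in corners)
    bmin = min(p[1] for p in corners)
    bmax = max(p[1] for p in corners)
    c_lo, c_hi = int(amin / pitch) - 1, int(amax / pitch) + 1
    r_lo, r_hi = int(bmin / pitch) - 1, int(bmax / pitch) + 1
    n_rows = grid_rows if grid_rows is not None else cfg.grid_rows
    if c_lo < 0 or c_hi >= cfg.grid_cols or r_lo < 0 or (
        n_rows is not None and r_hi >= n_rows
    ):
        raise ValueError(
            f"footfall {index} at {heel_pos} does not fit on the mat grid"
        )

    rows, cols = np.meshgrid(
        np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    centers = np.column_stack(((cols + 0.5) * pitch, (rows + 0.5) * pitch))
    rel = centers - origin
    u_mm = rel @ direction
    v_mm = rel @ lateral  # +v = lateral side of this foot
    u = u_mm / fl
    inside_u = (u >= 0.0) & (u <= 1.0)
    base = _half_width(np.clip(u, 0.0, 1.0), fw)
    w_med = base * (
        1.0 - cfg.arch_depth * np.exp(-(((np.clip(u, 0, 1) - 0.45) / 0.20) ** 2))
    )
    inside = inside_u & np.where(v_mm >= 0, v_mm <= base, -v_mm <= w_med)
    rows, cols, u, v_mm, base = rows[inside], cols[inside], u[inside], v_mm[inside], base[inside]
    if rows.size < 9:
        raise ValueError(f"footfall {index}: template degenerated to {rows.size} cells")

    # contact-wave knots; u78 is the along-foot position of the cell whose
    # activation completes the 78% foot-flat criterion.  The heel pad
    # (u <= 0.10) strikes as one impact and the toe pad (u >= 0.92)
    # releases as one push-off, so the COP is never pinned to a single
    # barely-loaded corner cell at the ends of stance.
    order = np.argsort(u, kind="stable")
    m = math.ceil(0.78 * rows.size)
    u78 = min(max(float(u[order][m - 1]), 1.0 / 3.0 + 0.02), 0.98)
    on_knots_u = np.array([0.10, 1.0 / 3.0, u78, 1.0])
    on_knots_g = np.array(
        [0.0, mon_f, fft_f, min(fft_f + 0.06, hot_f - 0.01)]
    )
    off_start = max(fft_f + 0.02, hot_f - 0.18)
    off_knots_u = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 0.92])
    off_knots_g = np.array([off_start, hot_f, mof_f, 1.0])

    on_ms = t0_ms + stance * np.interp(u, on_knots_u, on_knots_g)
    off_ms = t0_ms + stance * np.interp(u, off_knots_u, off_knots_g)
    period = 1000.0 / cfg.sampling_rate
    if cfg.timing_jitter_ms > 0:
        on_ms = on_ms + rng.normal(0.0, cfg.timing_jitter_ms, size=on_ms.shape)
        off_ms = off_ms + rng.normal(0.0, cfg.timing_jitter_ms, size=off_ms.shape)
    else:
        # a thresholded sensor array reports switch times on the device
        # clock; without explicit jitter the planted times sit on it too
        on_ms = np.round(on_ms / period) * period
        off_ms = np.round(off_ms / period) * period
    off_ms = np.maximum(off_ms, on_ms + 2.5 * period)

    v_hat = np.clip(v_mm / np.maximum(base, 1e-9), -1.0, 1.0)
    amp = 1.0 + cfg.ml_pressure_gain * (-np.cos(2.0 * np.pi * u)) * v_hat
    amp = np.clip(amp, 0.1, None)

    cells = {
        (int(r), int(c)): (float(on), float(off), float(a), float(vh))
        for r, c, on, off, a, vh in zip(rows, cols, on_ms, off_ms, amp, v_hat)
    }
    if cfg.noise_rate > 0:
        cells = _add_flicker(cells, cfg, rng, t0_ms, stance)

    return _ground_truth(
        cells, index, side, pitch, theta,
        t0_ms=t0_ms, stance_dur_ms=stance, ml_time_gain=cfg.ml_time_gain,
        sensor_threshold=cfg.sensor_threshold,
    )


def _add_flicker(cells, cfg, rng, t0_ms, stance):
    """Spurious brief activations on cells adjacent to the footfall boundary."""
    n_noise = rng.binomial(len(cells), min(cfg.noise_rate, 1.0))
    cell_set = set(cells)
    neighbours = sorted(
        {
            (r + dr, c + dc)
            for r, c in cell_set
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        }
        - cell_set
    )
    out = dict(cells)
    for _ in range(int(n_noise)):
        if not neighbours:
            break
        rc = neighbours[rng.integers(len(neighbours))]
        if rc[0] < 0 or rc[1] < 0:
            continue
        t = t0_ms + stance * rng.uniform(0.1, 0.9)
        out[rc] = (float(t), float(t + 2.0 * 1000.0 / cfg.sampling_rate), 0.15, 0.0)
    return out


def _ground_truth(
    cells, index, side, pitch, theta_placed, t0_ms, stance_dur_ms, ml_time_gain,
    sensor_threshold,
) -> TrueFootfall:
    """Detector-rule events and axis evaluated on the continuous cell times."""
    ff = Footfall(
        cells={rc: (on, off) for rc, (on, off, _amp, _vh) in cells.items()},
        index=index,
        side=side,
    )
    axis = estimate_axis(ff, pitch, walking_axis="vertical")
    events = detect_events(ff, axis)
    return TrueFootfall(
        index=index,
        side=side,
        cells=cells,
        heel=axis.heel,
        toe=axis.toe,
        theta_c=axis.theta_c,
        theta_placed=theta_placed,
        foot_length=axis.foot_length,
        foot_width=axis.foot_width,
        events=events,
        cell_pitch=pitch,
        t0_ms=t0_ms,
        stance_dur_ms=stance_dur_ms,
        ml_time_gain=ml_time_gain,
        sensor_threshold=sensor_threshold,
        thirds=axis.thirds,
    )


# ----------------------------------------------------------------------
# recordings and cohorts


@dataclass
class GroundTruth:
    """Planted truth of one synthetic recording."""

    footfalls: list[TrueFootfall]
    traits: SubjectTraits

    @property
    def n_footfalls(self) -> int:
        return len(self.footfalls)

    @property
    def sides(self) -> list[str]:
        return [ff.side for ff in self.footfalls]


def generate_recording(
    cfg: SynthConfig, traits: SubjectTraits | None = None, seed: int | None = None
) -> tuple[MatRecording, GroundTruth]:
    """One subject's walking trial: alternating footfalls progressing up the mat.

    Deterministic for a fixed config and seed (``seed`` defaults to
    ``cfg.seed``).  The grid is auto-sized to the walk when
    ``cfg.grid_rows`` is None; an explicit grid that cannot hold the
    requested steps raises ``ValueError``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if traits is None:
        traits = draw_subject(cfg, rng)

    margin = 60.0
    a_center = cfg.grid_cols * cfg.cell_pitch_mm / 2.0
    step_half = 0.5 * cfg.step_width_mm[0]

    truths: list[TrueFootfall] = []
    # auto-sized grids get room for the whole walk before placing
    needed_b = margin + cfg.n_steps * traits.step_length_mm + traits.foot_length + margin
    grid_rows = (
        cfg.grid_rows
        if cfg.grid_rows is not None
        else int(math.ceil(needed_b / cfg.cell_pitch_mm))
    )
    for i in range(cfg.n_steps):
        side = "left" if i % 2 == 0 else "right"
        lateral_sign = -1.0 if side == "left" else 1.0
        a0 = a_center + lateral_sign * (
            step_half + rng.normal(0.0, cfg.step_width_mm[1])
        )
        b0 = margin + i * traits.step_length_mm
        t0 = i * traits.step_time_ms
        ff = generate_footfall(
            cfg,
            traits,
            rng,
            heel_pos=(a0, b0),
            side=side,
            t0_ms=t0,
            index=i + 1,
            grid_rows=grid_rows,
        )
        truths.append(ff)

    frames: dict[int, list[tuple[int, int, float]]] = {}
    period = 1000.0 / cfg.sampling_rate
    for ff in truths:
        for (r, c), (on, off, amp, vhat) in ff.cells.items():
            f0 = int(math.ceil(on / period - 1e-6))
            f1 = int(math.floor(off / period + 1e-6))
            fs = np.arange(f0, f1 + 1)
            p = _pressure_profile(
                fs * period, on, off, amp, vhat,
                ff.t0_ms, ff.stance_dur_ms, ff.ml_time_gain,
                ff.sensor_threshold,
            )
            for f, pf in zip(fs, p):
                if pf > 0:
                    frames.setdefault(int(f), []).append((r, c, float(pf)))

    frame_list = [
        (f, np.array(frames[f], dtype=float)) for f in sorted(frames)
    ]
    rec = MatRecording(
        grid_rows=grid_rows,
        grid_cols=cfg.grid_cols,
        frames=frame_list,
        sampling_rate=cfg.sampling_rate,
        cell_pitch=cfg.cell_pitch_mm,
        walking_axis="vertical",
    )
    return rec, GroundTruth(footfalls=truths, traits=traits)


def generate_cohort(
    cfg: SynthConfig,
) -> dict[str, tuple[MatRecording, GroundTruth]]:
    """Independent recordings for ``cfg.n_subjects`` subjects (seeded per subject)."""
    out = {}
    for i in range(cfg.n_subjects):
        sub_seed = (cfg.seed * 100003 + i) % (2**31 - 1)
        rec, truth = generate_recording(cfg, seed=sub_seed)
        out[f"S{i + 1:03d}"] = (rec, truth)
    return out


# ----------------------------------------------------------------------
# parameter matrices and footprints


def generate_parameter_matrix(
    n: int,
    k: int,
    mu: float = 0.0,
    sigma_between: float = 1.0,
    sigma_within: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """n x k matrix value(i,j) = mu + b_i + e_ij and its true ICC.

    b ~ N(0, sigma_between^2) per subject, e ~ N(0, sigma_within^2) per
    footfall; true ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2) (1.0 when both
    are zero by convention of a perfectly repeatable measurement).
    """
    if sigma_between < 0 or sigma_within < 0:
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_between, size=(n, 1))
    e = rng.normal(0.0, sigma_within, size=(n, k))
    total = sigma_between**2 + sigma_within**2
    true_icc = 1.0 if total == 0 else sigma_between**2 / total
    return mu + b + e, true_icc


def generate_footprint(
    foot_length_mm: float = 240.0,
    foot_width_mm: float = 100.0,
    arch_depth: float = 0.6,
    cell_pitch_mm: float = 8.5,
    with_toes: bool = True,
    toe_mask: bool = False,
    seed: int = 0,
) -> FootprintGrid:
    """Static synthetic footprint: waisted sole plus optionally detached toes.

    The sole spans 80% of the foot length; five toe blobs sit distally with
    a one-row gap, so the toe-exclusion heuristic has something to find.
    With ``toe_mask=True`` the toe cells are flagged explicitly instead.
    """
    rng = np.random.default_rng(seed)
    pitch = cell_pitch_mm
    sole_len = 0.8 * foot_length_mm
    margin = 2 * pitch
    cells: list[tuple[int, int, float]] = []
    toe_cells: set[tuple[int, int]] = set()

    n_rows = int((foot_length_mm + 2 * margin) / pitch) + 2
    n_cols = int((foot_width_mm + 2 * margin) / pitch) + 2
    a_center = (n_cols * pitch) / 2.0
    for r in range(n_rows):
        for c in range(n_cols):
            a, b = (c + 0.5) * pitch, (r + 0.5) * pitch
            u_mm = b - margin
            if not 0.0 <= u_mm <= sole_len:
                continue
            u = u_mm / sole_len
            v = a - a_center  # +v = lateral for a right foot
            base = float(_half_width(np.array([u]), foot_width_mm)[0])
            w_med = base * (1.0 - arch_depth * math.exp(-(((u - 0.45) / 0.20) ** 2)))
            if (v >= 0 and v <= base) or (v < 0 and -v <= w_med):
                cells.append((r, c, 1.0))

    if with_toes:
        sole_top = margin + sole_len
        gap = 1.8 * pitch
        toe_radii = [11.0, 8.0, 7.0, 6.5, 6.0]
        toe_pos = np.linspace(-0.38, 0.38, 5) * foot_width_mm
        for radius, v0 in zip(toe_radii, toe_pos[::-1]):  # hallux medial
            b0 = sole_top + gap + radius + rng.uniform(0, 0.3 * pitch)
            a0 = a_center + v0
            for r in range(n_rows):
                for c in range(n_cols):
                    a, b = (c + 0.5) * pitch, (r + 0.5) * pitch
                    if (a - a0) ** 2 + (b - b0) ** 2 <= radius**2:
                        cells.append((r, c, 1.0))
                        toe_cells.add((r, c))

    # deduplicate (toe circles may overlap)
    seen = {}
    for r, c, p in cells:
        seen[(r, c)] = p
    arr = np.array([[r, c, p] for (r, c), p in sorted(seen.items())], dtype=float)
    return FootprintGrid(
        arr,
        cell_pitch=pitch,
        toe_mask=frozenset(toe_cells) if (toe_mask and toe_cells) else None,
    )
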