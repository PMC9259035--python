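"""Stochastic simulation of kinetochore transport on dynamic microtubules.

The model: a kinetochore binds the lateral surface of a microtubule grown
from a seed (the minus end, at position 0).  With probability ``p_motile`` it
is motile, alternating exponentially distributed plus-end-directed runs
(velocity ``v_run``) and pauses — a memoryless two-state Markov process whose
stationary run occupancy is ``t_run_mean / (t_run_mean + t_pause_mean)``.
The free plus end grows at ``v_growth`` and catastrophes as a Poisson process
with rate ``f_cat`` (no rescue), after which it shrinks at ``v_depol_free``.
When the gap between kinetochore and plus end closes to within one kymograph
pixel, the attachment converts irreversibly from lateral to end-on: the
kinetochore snaps to the tip, the microtubule is forced into
kinetochore-coupled depolymerization, and the pair thereafter alternates
tip-moving (both retreating at ``v_tip_track``) and tip-paused dwells.  The
microtubule never regrows after conversion and the kinetochore never
detaches.

Events are sampled exactly in continuous time and only discretized to the
frame grid for output, so dwell statistics carry no frame-interval bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .presets import GenotypePreset

__all__ = [
    "PIXEL_UM",
    "MicrotubuleTrace",
    "Trajectory",
    "TrajectorySet",
    "simulate_microtubule",
    "simulate_kinetochore",
    "simulate_cohort",
    "simulate_rescue",
]

#: Kymograph pixel size (µm); also the lateral→end-on conversion tolerance.
PIXEL_UM = 0.0722

_LATERAL_RUN = "lateral_run"
_LATERAL_PAUSE = "lateral_pause"
_TIP_MOVE = "tip_move"
_TIP_PAUSE = "tip_pause"

STATE_LABELS = (_LATERAL_RUN, _LATERAL_PAUSE, _TIP_MOVE, _TIP_PAUSE)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _frame_times(duration: float, frame_interval: float) -> np.ndarray:
    n = int(round(duration / frame_interval))
    if n < 1:
        raise ValueError("duration must cover at least one frame")
    return np.arange(n) * float(frame_interval)


# ---------------------------------------------------------------------------
# Microtubule dynamic instability (free plus end, no rescue)
# ---------------------------------------------------------------------------

@dataclass
class MicrotubuleTrace:
    """A free plus-end trajectory with its continuous-time description."""

    times: np.ndarray          # s
    position: np.ndarray       # plus-end position (µm), seed at 0
    phase: np.ndarray          # 'growth' | 'shrink' per frame
    L0: float                  # initial length (µm)
    catastrophe_time: float | None   # s, None if none within the movie
    v_growth: float            # µm/min
    v_depol_free: float        # µm/min

    @property
    def n_catastrophes(self) -> int:
        return int(self.catastrophe_time is not None)

    def position_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Exact continuous plus-end position (µm) at time ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        tc = math.inf if self.catastrophe_time is None else self.catastrophe_time
        grow = self.L0 + self.v_growth / 60.0 * np.minimum(t, tc)
        shrink = self.v_depol_free / 60.0 * np.clip(t - tc, 0.0, None)
        return np.maximum(grow - shrink, 0.0)


def simulate_microtubule(
    preset: GenotypePreset,
    duration: float,
    frame_interval: float,
    rng,
    L0: float | None = None,
) -> MicrotubuleTrace:
    """Simulate one free microtubule plus end.

    The plus end grows at ``preset.v_growth`` from an initial length drawn
    uniformly from ``preset.L0_range`` (or ``L0`` if given), undergoes at most
    one catastrophe (exponential waiting time at rate ``preset.f_cat``), then
    shrinks at ``preset.v_depol_free`` down to the seed and stays there.
    """
    if duration <= 0 or frame_interval <= 0:
        raise ValueError("duration and frame_interval must be positive")
    rng = _as_rng(rng)
    times = _frame_times(duration, frame_interval)
    if L0 is None:
        L0 = float(rng.uniform(*preset.L0_range))
    if L0 < 0:
        raise ValueError("L0 must be non-negative")
    if preset.f_cat > 0:
        t_cat = float(rng.exponential(60.0 / preset.f_cat))
    else:
        t_cat = math.inf
    catastrophe_time = t_cat if t_cat < duration else None
    trace = MicrotubuleTrace(
        times=times,
        position=np.empty_like(times),
        phase=np.where(times < t_cat, "growth", "shrink").astype("<U6"),
        L0=L0,
        catastrophe_time=catastrophe_time,
        v_growth=preset.v_growth,
        v_depol_free=preset.v_depol_free,
    )
    trace.position = np.asarray(trace.position_at(times), dtype=float)
    return trace


# ---------------------------------------------------------------------------
# Kinetochore trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ground-truth kinetochore + plus-end positions, states and attachment."""

    times: np.ndarray         # s, uniform grid
    kt_position: np.ndarray   # µm from the seed
    mt_plus_end: np.ndarray   # µm from the seed
    state: np.ndarray         # one of STATE_LABELS per frame
    attachment: np.ndarray    # 'lateral' | 'end_on' per frame
    motile: bool              # drawn motile at t=0
    rng_seed: int | None = None
    rescued: bool = False     # became motile at an add-back switch

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def end_on_frame(self) -> int | None:
        idx = np.nonzero(self.attachment == "end_on")[0]
        return int(idx[0]) if idx.size else None


@dataclass
class TrajectorySet:
    """A cohort of trajectories simulated under one preset."""

    trajectories: list[Trajectory]
    preset: GenotypePreset
    frame_interval: float
    duration: float

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("TrajectorySet requires at least one trajectory")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tr in enumerate(self.trajectories):
            rows.append(pd.DataFrame({
                "trajectory_id": i,
                "frame": np.arange(tr.n_frames),
                "time_s": tr.times,
                "kt_um": tr.kt_position,
                "mt_end_um": tr.mt_plus_end,
                "state": tr.state,
                "attachment": tr.attachment,
                "motile": tr.motile,
                "rng_seed": -1 if tr.rng_seed is None else tr.rng_seed,
                "rescued": tr.rescued,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, preset: GenotypePreset) -> "TrajectorySet":
        df = pd.read_csv(path)
        trajectories = []
        for _, g in df.groupby("trajectory_id", sort=True):
            g = g.sort_values("frame")
            seed = int(g["rng_seed"].iloc[0])
            trajectories.append(Trajectory(
                times=g["time_s"].to_numpy(float),
                kt_position=g["kt_um"].to_numpy(float),
                mt_plus_end=g["mt_end_um"].to_numpy(float),
                state=g["state"].to_numpy(str),
                attachment=g["attachment"].to_numpy(str),
                motile=bool(g["motile"].iloc[0]),
                rng_seed=None if seed < 0 else seed,
                rescued=bool(g["rescued"].iloc[0]),
            ))
        t0 = trajectories[0].times
        fi = float(t0[1] - t0[0]) if len(t0) > 1 else 0.0
        return cls(trajectories=trajectories, preset=preset,
                   frame_interval=fi, duration=fi * len(t0))


# --- continuous-time event engine ------------------------------------------

@dataclass
class _Segment:
    t0: float
    kt0: float
    v_kt: float       # µm/s
    mt0: float
    v_mt: float       # µm/s
    state: str
    attach: str


def _draw_lateral_state(preset: GenotypePreset, rng) -> tuple[str, float]:
    if rng.random() < preset.lateral_moving_fraction:
        return _LATERAL_RUN, float(rng.exponential(preset.t_run_mean))
    return _LATERAL_PAUSE, float(rng.exponential(preset.t_pause_mean))


def _draw_tip_state(preset: GenotypePreset, rng) -> tuple[str, float]:
    if rng.random() < preset.tip_moving_fraction:
        return _TIP_MOVE, float(rng.exponential(preset.t_tipmove_mean))
    return _TIP_PAUSE, float(rng.exponential(preset.t_tippause_mean))


def _simulate_trajectory(
    phases: Sequence[tuple[float, GenotypePreset]],
    duration: float,
    frame_interval: float,
    rng: np.random.Generator,
    conversion_tol_um: float = PIXEL_UM,
    p_rescue: float = 0.0,
    mt_init: tuple[float, float, float, float] | None = None,
    motile: bool | None = None,
    x0: float | None = None,
    rng_seed: int | None = None,
) -> Trajectory:
    """Exact event-driven simulation of one kinetochore on one microtubule.

    ``phases`` is a schedule of (start time, preset); at each later phase
    boundary a still-immobile lateral kinetochore becomes motile with
    probability ``p_rescue`` (add-back experiment) and all dwells/catastrophe
    clocks are redrawn from the new preset (exact for exponential dwells).
    ``mt_init`` optionally fixes the free microtubule as
    ``(L0, t_cat, v_growth, v_depol_free)``.
    """
    preset = phases[0][1]
    switches = [(t, p) for t, p in phases[1:]]

    # Microtubule initial state
    if mt_init is None:
        L0 = float(rng.uniform(*preset.L0_range))
        t_cat = (float(rng.exponential(60.0 / preset.f_cat))
                 if preset.f_cat > 0 else math.inf)
        v_g, v_d = preset.v_growth, preset.v_depol_free
    else:
        L0, t_cat, v_g, v_d = mt_init
        t_cat = math.inf if t_cat is None else t_cat

    # Kinetochore initial state
    if x0 is None:
        x0 = float(rng.uniform(*preset.x0_fraction_range)) * L0
    if motile is None:
        motile = bool(rng.random() < preset.p_motile)
    motile0 = bool(motile)
    was_rescued = False

    x = float(x0)
    mt = float(L0)
    attach = "lateral"
    mt_phase = "growth" if t_cat > 0 else "shrink"
    if motile:
        state, dwell = _draw_lateral_state(preset, rng)
    else:
        state, dwell = _LATERAL_PAUSE, math.inf

    segments: list[_Segment] = []
    t = 0.0
    eps = 1e-9
    while t < duration - eps:
        if state == _LATERAL_RUN:
            v_kt = preset.v_run / 60.0
        elif state == _TIP_MOVE:
            v_kt = -preset.v_tip_track / 60.0
        else:
            v_kt = 0.0
        if attach == "end_on":
            v_mt = v_kt
        else:
            v_mt = (v_g / 60.0) if mt_phase == "growth" else (-v_d / 60.0)

        # candidate event times (absolute)
        t_dwell = t + dwell if math.isfinite(dwell) else math.inf
        t_catast = t_cat if (attach == "lateral" and mt_phase == "growth") else math.inf
        t_switch = switches[0][0] if switches else math.inf
        t_conv = math.inf
        if attach == "lateral":
            gap = mt - x
            closing = v_mt - v_kt
            if gap <= conversion_tol_um + eps:
                t_conv = t
            elif closing < 0:
                t_conv = t + (gap - conversion_tol_um) / (-closing)
        t_floor = math.inf
        if attach == "end_on" and v_kt < 0 and x > 0:
            t_floor = t + x / (-v_kt)

        t_next = min(duration, t_dwell, t_catast, t_switch, t_conv, t_floor)
        if t_next > t + eps:
            segments.append(_Segment(t, x, v_kt, mt, v_mt, state, attach))
        dt = t_next - t
        x += v_kt * dt
        mt = x if attach == "end_on" else mt + v_mt * dt
        if math.isfinite(dwell):
            dwell -= dt
        t = t_next
        if t >= duration - eps:
            break

        # apply the earliest event; ties resolved in this priority order
        if t_conv <= t_next + eps and attach == "lateral":
            attach = "end_on"
            x = mt = max(x, mt)   # snap to the tip (jump <= one pixel)
            mt_phase = "coupled"
            state, dwell = _draw_tip_state(preset, rng)
        elif t_floor <= t_next + eps and attach == "end_on" and math.isfinite(t_floor):
            x = mt = 0.0
            state, dwell = _TIP_PAUSE, math.inf
        elif t_catast <= t_next + eps and mt_phase == "growth" and math.isfinite(t_catast):
            mt_phase = "shrink"
            t_cat = math.inf
        elif math.isfinite(t_dwell) and t_dwell <= t_next + eps:
            if attach == "lateral":
                if state == _LATERAL_RUN:
                    state, dwell = _LATERAL_PAUSE, float(rng.exponential(preset.t_pause_mean))
                else:
                    state, dwell = _LATERAL_RUN, float(rng.exponential(preset.t_run_mean))
            else:
                if state == _TIP_MOVE:
                    state, dwell = _TIP_PAUSE, float(rng.exponential(preset.t_tippause_mean))
                else:
                    state, dwell = _TIP_MOVE, float(rng.exponential(preset.t_tipmove_mean))
        elif switches and t_switch <= t_next + eps:
            _, preset = switches.pop(0)
            if attach == "lateral" and not motile:
                if rng.random() < p_rescue:
                    motile = True
                    was_rescued = True
                    state, dwell = _draw_lateral_state(preset, rng)
            elif attach == "lateral":
                # memoryless: redraw the residual dwell at the new rate
                mean = (preset.t_run_mean if state == _LATERAL_RUN
                        else preset.t_pause_mean)
                dwell = float(rng.exponential(mean))
            else:
                mean = (preset.t_tipmove_mean if state == _TIP_MOVE
                        else preset.t_tippause_mean)
                dwell = float(rng.exponential(mean))
            v_g, v_d = preset.v_growth, preset.v_depol_free
            if mt_phase == "growth":
                t_cat = (t + float(rng.exponential(60.0 / preset.f_cat))
                         if preset.f_cat > 0 else math.inf)

    if not segments:   # degenerate: event at t=0 consumed everything
        segments.append(_Segment(0.0, x, 0.0, mt, 0.0, state, attach))

    # discretize to the frame grid
    times = _frame_times(duration, frame_interval)
    t0s = np.array([s.t0 for s in segments])
    idx = np.clip(np.searchsorted(t0s, times, side="right") - 1, 0, len(segments) - 1)
    kt0 = np.array([s.kt0 for s in segments])[idx]
    vkt = np.array([s.v_kt for s in segments])[idx]
    mt0 = np.array([s.mt0 for s in segments])[idx]
    vmt = np.array([s.v_mt for s in segments])[idx]
    dt_in = times - t0s[idx]
    kt_pos = kt0 + vkt * dt_in
    mt_pos = mt0 + vmt * dt_in
    states = np.array([s.state for s in segments], dtype="<U13")[idx]
    attaches = np.array([s.attach for s in segments], dtype="<U7")[idx]
    end_on = attaches == "end_on"
    mt_pos = np.where(end_on, kt_pos, mt_pos)
    return Trajectory(
        times=times,
        kt_position=kt_pos,
        mt_plus_end=mt_pos,
        state=states,
        attachment=attaches,
        motile=motile0,
        rng_seed=rng_seed,
        rescued=was_rescued,
    )


def simulate_kinetochore(
    preset: GenotypePreset,
    mt: MicrotubuleTrace,
    rng,
    conversion_tol_um: float = PIXEL_UM,
    motile: bool | None = None,
    x0: float | None = None,
) -> Trajectory:
    """Simulate one kinetochore on a given free-microtubule trace.

    The free plus end follows ``mt`` until the lateral→end-on conversion;
    from conversion onward the microtubule is slaved to the kinetochore
    (kinetochore-coupled depolymerization, no regrowth).
    """
    rng = _as_rng(rng)
    duration = float(mt.times[-1] + (mt.times[1] - mt.times[0])) if len(mt.times) > 1 else float(mt.times[-1])
    frame_interval = float(mt.times[1] - mt.times[0])
    return _simulate_trajectory(
        [(0.0, preset)],
        duration=duration,
        frame_interval=frame_interval,
        rng=rng,
        conversion_tol_um=conversion_tol_um,
        mt_init=(mt.L0,
                 mt.catastrophe_time if mt.catastrophe_time is not None else math.inf,
                 mt.v_growth, mt.v_depol_free),
        motile=motile,
        x0=x0,
    )


def _child_seeds(seed, n: int) -> np.ndarray:
    """Stable per-trajectory integer seeds (< 2**31) from a master seed."""
    if isinstance(seed, np.random.Generator):
        return seed.integers(0, 2**31 - 1, size=n)
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31 - 1)


def simulate_cohort(
    preset: GenotypePreset,
    n: int,
    duration: float,
    frame_interval: float,
    rng,
    conversion_tol_um: float = PIXEL_UM,
) -> TrajectorySet:
    """Simulate ``n`` independent kinetochore trajectories under one preset."""
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    if duration <= 0 or frame_interval <= 0:
        raise ValueError("duration and frame_interval must be positive")
    seeds = _child_seeds(rng, n)
    trajectories = []
    for s in seeds:
        child = np.random.default_rng(int(s))
        traj = _simulate_trajectory(
            [(0.0, preset)], duration, frame_interval, child,
            conversion_tol_um=conversion_tol_um, rng_seed=int(s),
        )
        trajectories.append(traj)
    return TrajectorySet(trajectories, preset, frame_interval, duration)


def simulate_rescue(
    preset_before: GenotypePreset,
    preset_after: GenotypePreset,
    t_switch: float,
    p_rescue: float,
    n: int,
    rng,
    duration: float = 1800.0,
    frame_interval: float = 5.0,
    conversion_tol_um: float = PIXEL_UM,
    all_immobile: bool = False,
) -> TrajectorySet:
    """Simulate the kinesin add-back experiment.

    Kinetochores evolve under ``preset_before`` until ``t_switch``; at the
    switch each kinetochore that is still immobile becomes motile with
    probability ``p_rescue`` and thereafter follows ``preset_after``
    kinetics.  With ``all_immobile=True`` every kinetochore starts immobile
    — the add-back assay scores laterally bound, stationary kinetochores —
    regardless of ``preset_before.p_motile``.
    """
    if not 0.0 <= p_rescue <= 1.0:
        raise ValueError("p_rescue must lie in [0, 1]")
    if not 0.0 < t_switch < duration:
        raise ValueError("t_switch must lie strictly inside the movie")
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    seeds = _child_seeds(rng, n)
    trajectories = []
    for s in seeds:
        child = np.random.default_rng(int(s))
        traj = _simulate_trajectory(
            [(0.0, preset_before), (float(t_switch), preset_after)],
            duration, frame_interval, child,
            conversion_tol_um=conversion_tol_um,
            p_rescue=p_rescue,
            motile=False if all_immobile else None,
            rng_seed=int(s),
        )
        trajectories.append(traj)
    return TrajectorySet(trajectories, preset_after, frame_interval, duration)
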