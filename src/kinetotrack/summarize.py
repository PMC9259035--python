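"""Per-track motility statistics and cohort summaries.

Statistics follow the published definitions: the per-track velocity is the
(duration-weighted) mean of its run-segment velocities — pauses are reported
separately as time fractions — run length is the net displacement of one
uninterrupted run, and cohort dispersion is the standard error of the mean
over tracks.  Tracks with no runs contribute to the motile-fraction
denominator but are excluded from velocity averages.  Pooled time fractions
are computed over tracks that moved at all (lateral) or that reached the
plus end (tip): a kinetochore that never moves has no measurable run/pause
partition, only an all-paused record.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .segment import Segmentation
from .tracking import Track

__all__ = ["MotilitySummary", "CohortSummary", "summarize_track", "summarize_cohort"]


@dataclass
class MotilitySummary:
    """Motility statistics of a single kinetochore track."""

    trajectory_id: str | int
    mean_run_velocity: float          # µm/min over run_plus segments; NaN if none
    gross_lateral_velocity: float     # µm/min net displacement over lateral time
    mean_tip_velocity: float          # µm/min magnitude over tip_track segments; NaN if none
    run_lengths: np.ndarray           # µm, one per run_plus segment
    n_runs: int
    lateral_moving_fraction: float    # of lateral frames; NaN if no lateral frames
    tip_moving_fraction: float        # of tip frames; NaN if no tip frames
    moved_at_all: bool
    reached_plus_end: bool
    n_lateral_frames: int
    n_lateral_run_frames: int
    n_tip_frames: int
    n_tip_track_frames: int


def summarize_track(seg: Segmentation, track: Track,
                    frame_interval: float = 5.0) -> MotilitySummary:
    """Reduce one segmentation to the published per-track statistics."""
    x = np.asarray(track.positions_um, dtype=float)
    runs = seg.runs()
    tips = seg.tip_tracks()
    end_on = seg.end_on_frame
    n_lateral = seg.n_frames if end_on is None else end_on
    n_tip = seg.n_frames - n_lateral

    run_lengths = np.array([x[s.stop - 1] - x[s.start] for s in runs])
    run_w = np.array([s.n_frames for s in runs], dtype=float)
    tip_w = np.array([s.n_frames for s in tips], dtype=float)
    mean_run_v = (float(np.average([s.velocity_um_min for s in runs], weights=run_w))
                  if runs else math.nan)
    mean_tip_v = (float(np.average([abs(s.velocity_um_min) for s in tips], weights=tip_w))
                  if tips else math.nan)

    n_run_frames = int(run_w.sum())
    n_tip_track_frames = int(tip_w.sum())
    if n_lateral > 1:
        lateral_minutes = (n_lateral - 1) * frame_interval / 60.0
        gross = float((x[n_lateral - 1] - x[0]) / lateral_minutes)
    else:
        gross = math.nan

    return MotilitySummary(
        trajectory_id=track.trajectory_id,
        mean_run_velocity=mean_run_v,
        gross_lateral_velocity=gross,
        mean_tip_velocity=mean_tip_v,
        run_lengths=run_lengths,
        n_runs=len(runs),
        lateral_moving_fraction=(n_run_frames / n_lateral if n_lateral else math.nan),
        tip_moving_fraction=(n_tip_track_frames / n_tip if n_tip else math.nan),
        moved_at_all=len(runs) >= 1,
        reached_plus_end=end_on is not None,
        n_lateral_frames=n_lateral,
        n_lateral_run_frames=n_run_frames,
        n_tip_frames=n_tip,
        n_tip_track_frames=n_tip_track_frames,
    )


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan, math.nan
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))


@dataclass
class CohortSummary:
    """Cohort-level statistics (mean ± SEM over tracks, fractions, histograms)."""

    n_tracks: int
    mean_run_velocity: float
    sem_run_velocity: float
    mean_tip_velocity: float
    sem_tip_velocity: float
    mean_run_length: float            # pooled over all runs
    sem_run_length: float
    mean_n_runs: float
    sem_n_runs: float
    fraction_moved: float
    fraction_reached_end: float
    lateral_moving_fraction: float    # pooled frames, tracks that moved
    tip_moving_fraction: float        # pooled frames, tracks that reached the end
    mean_gross_lateral_velocity: float
    sem_gross_lateral_velocity: float
    velocity_histogram: pd.DataFrame = field(repr=False)
    run_length_histogram: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if not isinstance(v, pd.DataFrame)}
        d["velocity_histogram"] = self.velocity_histogram.to_dict(orient="list")
        d["run_length_histogram"] = self.run_length_histogram.to_dict(orient="list")
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_cohort(summaries: list[MotilitySummary],
                     hist_bin_width: float = 0.2) -> CohortSummary:
    """Aggregate per-track summaries into the published cohort statistics."""
    if not summaries:
        raise ValueError("cannot summarize an empty cohort")
    from .reporting import make_histogram

    run_v = np.array([s.mean_run_velocity for s in summaries])
    tip_v = np.array([s.mean_tip_velocity for s in summaries])
    gross_v = np.array([s.gross_lateral_velocity for s in summaries])
    pooled_lengths = np.concatenate([s.run_lengths for s in summaries]) \
        if any(s.n_runs for s in summaries) else np.array([])
    n_runs = np.array([s.n_runs for s in summaries], dtype=float)

    moved = [s for s in summaries if s.moved_at_all]
    reached = [s for s in summaries if s.reached_plus_end and s.n_tip_frames > 0]
    lat_frames = sum(s.n_lateral_frames for s in moved)
    lat_run_frames = sum(s.n_lateral_run_frames for s in moved)
    tip_frames = sum(s.n_tip_frames for s in reached)
    tip_track_frames = sum(s.n_tip_track_frames for s in reached)

    mv, sv = _mean_sem(run_v)
    mt, st = _mean_sem(tip_v)
    ml, sl = _mean_sem(pooled_lengths) if pooled_lengths.size else (math.nan, math.nan)
    mn, sn = _mean_sem(n_runs)
    mg, sg = _mean_sem(gross_v)

    return CohortSummary(
        n_tracks=len(summaries),
        mean_run_velocity=mv, sem_run_velocity=sv,
        mean_tip_velocity=mt, sem_tip_velocity=st,
        mean_run_length=ml, sem_run_length=sl,
        mean_n_runs=mn, sem_n_runs=sn,
        fraction_moved=len(moved) / len(summaries),
        fraction_reached_end=sum(s.reached_plus_end for s in summaries) / len(summaries),
        lateral_moving_fraction=(lat_run_frames / lat_frames if lat_frames else math.nan),
        tip_moving_fraction=(tip_track_frames / tip_frames if tip_frames else math.nan),
        mean_gross_lateral_velocity=mg, sem_gross_lateral_velocity=sg,
        velocity_histogram=make_histogram(run_v[~np.isnan(run_v)], hist_bin_width),
        run_length_histogram=make_histogram(pooled_lengths, hist_bin_width),
    )
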