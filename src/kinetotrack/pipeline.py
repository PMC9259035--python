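"""End-to-end orchestration: simulate → render → extract → segment → summarize.

`run_pipeline` ties the stages together for a set of genotype presets under
one master seed (child seeds are derived stably per genotype and stage, so a
stage can be re-run in isolation), writes machine-readable outputs beside a
resolved copy of the configuration, and reports group comparisons between
genotypes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .presets import GenotypePreset, make_preset
from .render import ImagingConfig, render_kymograph
from .reporting import GroupComparison, kruskal_wallis
from .segment import Segmentation, segment_track, default_threshold
from .simulate import Trajectory, TrajectorySet, simulate_cohort, PIXEL_UM
from .summarize import CohortSummary, MotilitySummary, summarize_cohort, summarize_track
from .tracking import Track, TrackLostError, extract_track, extract_plus_end

__all__ = [
    "PipelineConfig",
    "track_from_trajectory",
    "analyze_trajectory",
    "analyze_cohort",
    "run_pipeline",
]

log = logging.getLogger("kinetotrack")


@dataclass
class PipelineConfig:
    """Resolved configuration of one full pipeline run."""

    genotypes: list[str] = field(default_factory=lambda: ["WT", "kip3_null"])
    preset_overrides: dict = field(default_factory=dict)   # per-genotype field overrides
    n_per_cohort: int = 128
    duration: float = 1800.0
    frame_interval: float = 5.0
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    window_frames: int = 10
    threshold_nm_min: float | None = None     # None → unrounded one-pixel-per-window
    end_on_tol_um: float = PIXEL_UM
    use_rendering: bool = True                # False → segment ground-truth tracks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cohort <= 0:
            raise ValueError("n_per_cohort must be positive")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("duration and frame_interval must be positive")
        if isinstance(self.imaging, dict):
            self.imaging = ImagingConfig.from_dict(self.imaging)
        if (abs(self.imaging.frame_interval - self.frame_interval) > 1e-9
                or abs(self.imaging.duration - self.duration) > 1e-9):
            self.imaging = ImagingConfig.from_dict({
                **self.imaging.to_dict(),
                "frame_interval": self.frame_interval,
                "duration": self.duration,
            })

    def resolved_threshold(self) -> float:
        if self.threshold_nm_min is not None:
            return self.threshold_nm_min
        return default_threshold(self.frame_interval)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["imaging"] = self.imaging.to_dict()
        d["resolved_threshold_nm_min"] = self.resolved_threshold()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.pop("resolved_threshold_nm_min", None)
        return cls(**d)


def track_from_trajectory(traj: Trajectory, trajectory_id: str | int = 0) -> Track:
    """Ground-truth kinetochore positions as a fully visible Track."""
    return Track(
        trajectory_id=trajectory_id,
        frames=np.arange(traj.n_frames),
        positions_um=np.asarray(traj.kt_position, dtype=float),
        visible=np.ones(traj.n_frames, dtype=bool),
    )


def analyze_trajectory(
    traj: Trajectory,
    imaging: ImagingConfig | None,
    rng,
    window_frames: int = 10,
    threshold_nm_min: float | None = None,
    end_on_tol_um: float = PIXEL_UM,
    trajectory_id: str | int = 0,
) -> tuple[Track, np.ndarray, Segmentation, MotilitySummary]:
    """Measure one trajectory, optionally through the imaging model.

    With an :class:`ImagingConfig` the trajectory is rendered into a noisy
    blinking kymograph and both the kinetochore track and the plus-end series
    are re-extracted from the image; with ``imaging=None`` the ground-truth
    positions are segmented directly.
    """
    if imaging is not None:
        kymo = render_kymograph(traj, imaging, rng)
        track = extract_track(kymo, "kinetochore",
                              start_hint=traj.kt_position[0] / imaging.pixel_um,
                              trajectory_id=trajectory_id)
        mt_end = extract_plus_end(kymo, "microtubule")
        frame_interval = imaging.frame_interval
    else:
        track = track_from_trajectory(traj, trajectory_id)
        mt_end = np.asarray(traj.mt_plus_end, dtype=float)
        frame_interval = traj.frame_interval
    seg = segment_track(track, mt_end,
                        window_frames=window_frames,
                        threshold_nm_min=threshold_nm_min,
                        frame_interval=frame_interval,
                        end_on_tol_um=end_on_tol_um)
    summary = summarize_track(seg, track, frame_interval=frame_interval)
    return track, mt_end, seg, summary


def analyze_cohort(
    trajset: TrajectorySet,
    imaging: ImagingConfig | None,
    seed,
    window_frames: int = 10,
    threshold_nm_min: float | None = None,
    end_on_tol_um: float = PIXEL_UM,
) -> tuple[CohortSummary, list[MotilitySummary]]:
    """Run the measurement pipeline over a whole cohort."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(trajset))
    summaries: list[MotilitySummary] = []
    n_lost = 0
    for i, (traj, child) in enumerate(zip(trajset, children)):
        rng = np.random.default_rng(child)
        try:
            *_, summary = analyze_trajectory(
                traj, imaging, rng,
                window_frames=window_frames,
                threshold_nm_min=threshold_nm_min,
                end_on_tol_um=end_on_tol_um,
                trajectory_id=i,
            )
        except TrackLostError:
            n_lost += 1
            continue
        summaries.append(summary)
    if n_lost:
        log.warning("dropped %d/%d tracks lost during extraction", n_lost, len(trajset))
    return summarize_cohort(summaries), summaries


def _summaries_frame(summaries: list[MotilitySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        d = asdict(s)
        d["run_lengths"] = ";".join(f"{v:.6g}" for v in s.run_lengths)
        rows.append(d)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Simulate, analyze and summarize every requested genotype.

    Returns a report dictionary; when ``outdir`` is given, writes per-genotype
    cohort summaries (JSON), per-track tables and histograms (CSV), group
    comparisons, a human-readable report and the resolved configuration.
    """
    master = np.random.SeedSequence(config.seed)
    report: dict = {"seed": config.seed, "genotypes": {}}
    per_track_frames: dict[str, pd.DataFrame] = {}
    run_velocity_groups: dict[str, np.ndarray] = {}

    for gi, name in enumerate(config.genotypes):
        try:
            preset = make_preset(name, config.preset_overrides.get(name))
        except KeyError as exc:
            raise ValueError(f"[simulate:{name}] {exc}") from exc
        sim_ss, ana_ss = np.random.SeedSequence((config.seed, gi, 0)), \
            np.random.SeedSequence((config.seed, gi, 1))
        log.info("simulating %s cohort (n=%d)", name, config.n_per_cohort)
        trajset = simulate_cohort(
            preset, config.n_per_cohort, config.duration,
            config.frame_interval, np.random.default_rng(sim_ss),
        )
        cohort, summaries = analyze_cohort(
            trajset,
            config.imaging if config.use_rendering else None,
            ana_ss,
            window_frames=config.window_frames,
            threshold_nm_min=config.threshold_nm_min,
            end_on_tol_um=config.end_on_tol_um,
        )
        report["genotypes"][name] = cohort.to_dict()
        per_track_frames[name] = _summaries_frame(summaries)
        v = np.array([s.mean_run_velocity for s in summaries])
        run_velocity_groups[name] = v[~np.isnan(v)]

    if len([g for g in run_velocity_groups.values() if len(g)]) >= 2:
        usable = {k: v for k, v in run_velocity_groups.items() if len(v)}
        cmp_ = kruskal_wallis(usable)
        report["comparisons"] = [{
            "groups": list(cmp_.groups),
            "statistic": cmp_.statistic,
            "p_value": cmp_.p_value,
            "test_name": cmp_.test_name,
            "quantity": "mean_run_velocity",
        }]
    else:
        report["comparisons"] = []

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.resolved.yaml")
        for name, frame in per_track_frames.items():
            frame.to_csv(outdir / f"{name}.tracks.csv", index=False)
            summary = report["genotypes"][name]
            (outdir / f"{name}.cohort.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True))
            pd.DataFrame(summary["run_length_histogram"]).to_csv(
                outdir / f"{name}.run_length_hist.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        (outdir / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: dict) -> str:
    lines = [f"kinetotrack pipeline report (seed={report['seed']})", ""]
    for name, g in report["genotypes"].items():
        lines += [
            f"[{name}]  n={g['n_tracks']} tracks",
            (f"  run velocity      {g['mean_run_velocity']:.3f} ± "
             f"{g['sem_run_velocity']:.3f} µm/min (runs only; gross "
             f"{g['mean_gross_lateral_velocity']:.3f} µm/min)"),
            (f"  tip velocity      {g['mean_tip_velocity']:.3f} ± "
             f"{g['sem_tip_velocity']:.3f} µm/min"),
            (f"  run length        {g['mean_run_length']:.3f} ± "
             f"{g['sem_run_length']:.3f} µm"),
            (f"  moved / reached   {100 * g['fraction_moved']:.1f} % / "
             f"{100 * g['fraction_reached_end']:.1f} %"),
            (f"  moving time       lateral {100 * g['lateral_moving_fraction']:.1f} %,"
             f" tip {100 * g['tip_moving_fraction']:.1f} %"),
            "",
        ]
    for c in report.get("comparisons", []):
        lines.append(
            f"{c['test_name']} on {c['quantity']} across {', '.join(c['groups'])}: "
            f"H={c['statistic']:.3f}, p={c['p_value']:.3g}"
        )
    return "\n".join(lines) + "\n"
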