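"""Run/pause segmentation of kinetochore tracks.

The segmentation reproduces the published quantification rules:

* A centred least-squares slope is computed for every frame over a
  10-frame (50 s) sliding window; frames whose slope falls below one pixel
  (72.2 nm) per window — 86.64 nm/min, displayed as 86.7 — are *paused*.
  The inequality is strict ("less than a threshold slope ... paused"), so a
  slope exactly at the threshold counts as moving.
* Before the lateral→end-on transition, moving means plus-end-directed
  (``run_plus``); after it, moving means minus-end-directed tracking of the
  depolymerizing tip (``tip_track``).
* The transition is detected at the first frames where the kinetochore sits
  within one pixel of the plus end, and is irreversible.
* A moving segment must span at least one full window to count; shorter
  bursts are below the stated resolution and merge into the flanking pause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Track

__all__ = [
    "PIXEL_NM",
    "WINDOW_FRAMES",
    "Segment",
    "Segmentation",
    "threshold_nm_per_min",
    "default_threshold",
    "segment_track",
]

PIXEL_NM = 72.2
WINDOW_FRAMES = 10

_LATERAL_STATES = ("run_plus", "paused")
_TIP_STATES = ("tip_track", "tip_paused")


def threshold_nm_per_min(pixel_nm: float, window_frames: int, frame_interval: float) -> float:
    """Minimum resolvable slope: one pixel per window, in nm/min.

    ``threshold_nm_per_min(72.2, 10, 5)`` gives 86.64 nm/min (reported as
    86.7 at one decimal).
    """
    if pixel_nm <= 0 or window_frames <= 0 or frame_interval <= 0:
        raise ValueError("all threshold inputs must be positive")
    return pixel_nm / (window_frames * frame_interval) * 60.0


def default_threshold(frame_interval: float = 5.0) -> float:
    """The unrounded internal pause threshold (nm/min) at a given frame interval."""
    return threshold_nm_per_min(PIXEL_NM, WINDOW_FRAMES, frame_interval)


@dataclass(frozen=True)
class Segment:
    start: int            # first frame (inclusive)
    stop: int             # past-the-end frame
    state: str            # run_plus | paused | tip_track | tip_paused
    velocity_um_min: float

    @property
    def n_frames(self) -> int:
        return self.stop - self.start


@dataclass
class Segmentation:
    """A track partitioned into contiguous labelled segments."""

    segments: list[Segment]
    threshold_nm_min: float
    window_frames: int
    end_on_frame: int | None
    n_frames: int

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segmentation must contain at least one segment")
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.stop <= seg.start:
                raise ValueError("segments must be contiguous and non-empty")
            pos = seg.stop
        if pos != self.n_frames:
            raise ValueError("segments must cover the whole track")

    @property
    def labels(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype="<U10")
        for seg in self.segments:
            out[seg.start:seg.stop] = seg.state
        return out

    def runs(self) -> list[Segment]:
        return [s for s in self.segments if s.state == "run_plus"]

    def tip_tracks(self) -> list[Segment]:
        return [s for s in self.segments if s.state == "tip_track"]


def _sliding_slopes(x: np.ndarray, frame_interval: float, window: int) -> np.ndarray:
    """Centred least-squares slope per frame (µm/s), truncated at the ends.

    Frame ``i`` uses frames ``[i - window//2, i + window - window//2)``
    clipped to the track, so interior frames see exactly ``window`` points.
    """
    n = len(x)
    half = window // 2
    slopes = np.empty(n)
    # interior: full windows via one weighted dot product
    t = np.arange(window, dtype=float)
    w = (t - t.mean()) / np.sum((t - t.mean()) ** 2)   # LS slope weights
    if n >= window:
        from numpy.lib.stride_tricks import sliding_window_view
        win = sliding_window_view(x, window)           # shape (n-window+1, window)
        full = win @ w                                  # slope per window start k
        # window starting at k is centred on frame k + half
        slopes[half:half + len(full)] = full
    # edges (and any frame not covered above): truncated windows
    for i in list(range(min(half, n))) + list(range(half + max(n - window + 1, 0), n)):
        lo = max(0, i - half)
        hi = min(n, i + (window - half))
        tt = np.arange(hi - lo, dtype=float)
        xx = x[lo:hi]
        if len(xx) < 2:
            slopes[i] = 0.0
            continue
        tc = tt - tt.mean()
        slopes[i] = float(np.dot(tc, xx - xx.mean()) / np.dot(tc, tc))
    return slopes / frame_interval


def _segment_velocity(x: np.ndarray, frame_interval: float, start: int, stop: int) -> float:
    """Least-squares slope (µm/min) over frames [start, stop)."""
    if stop - start < 2:
        return 0.0
    t = np.arange(stop - start, dtype=float) * frame_interval
    xx = x[start:stop]
    tc = t - t.mean()
    return float(np.dot(tc, xx - xx.mean()) / np.dot(tc, tc)) * 60.0


def _runs_of(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of identical labels as (start, stop, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, str(labels[start])))
            start = i
    return out


def _detect_end_on(positions: np.ndarray, mt_end: np.ndarray,
                   tol_um: float, confirm: int = 2) -> int | None:
    """First frame from which the kinetochore stays within ``tol_um`` of the tip."""
    close = (mt_end - positions) <= tol_um
    n = len(close)
    for i in np.nonzero(close)[0]:
        stop = min(n, i + confirm)
        if np.all(close[i:stop]):
            return int(i)
    return None


def segment_track(
    track: Track,
    mt_end: np.ndarray | None = None,
    window_frames: int = WINDOW_FRAMES,
    threshold_nm_min: float | None = None,
    frame_interval: float = 5.0,
    end_on_tol_um: float = PIXEL_NM / 1000.0,
    min_moving_frames: int | None = None,
) -> Segmentation:
    """Partition a track into run/pause (lateral) and track/pause (tip) segments.

    Parameters
    ----------
    track:
        Kinetochore track (positions in µm on the frame grid).
    mt_end:
        Per-frame plus-end positions (µm).  If omitted, no lateral→end-on
        transition is detected and the whole track is treated as lateral.
    threshold_nm_min:
        Pause threshold; defaults to the unrounded one-pixel-per-window value
        (86.64 nm/min at 72.2 nm pixels, 10 frames, 5 s).
    min_moving_frames:
        Minimum span of a moving segment (defaults to one full window);
        shorter moving bursts are merged into the flanking pause.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    n = track.n_frames
    if n <= window_frames:
        raise ValueError(
            f"track has {n} frames; needs more than the {window_frames}-frame window"
        )
    if track.qc_excluded:
        raise ValueError("track flagged crossed/bundled; excluded from analysis")
    if threshold_nm_min is None:
        threshold_nm_min = threshold_nm_per_min(PIXEL_NM, window_frames, frame_interval)
    if min_moving_frames is None:
        min_moving_frames = window_frames

    x = np.asarray(track.positions_um, dtype=float)
    end_on = None
    if mt_end is not None:
        mt_end = np.asarray(mt_end, dtype=float)
        if len(mt_end) != n:
            raise ValueError("mt_end must share the track's frame grid")
        end_on = _detect_end_on(x, mt_end, end_on_tol_um)

    slopes_nm_min = _sliding_slopes(x, frame_interval, window_frames) * 60.0 * 1000.0
    fp_eps = 1e-6   # slope exactly at threshold counts as moving
    labels = np.empty(n, dtype="<U10")
    lateral = np.arange(n) < (n if end_on is None else end_on)
    moving_plus = slopes_nm_min >= threshold_nm_min - fp_eps
    moving_minus = slopes_nm_min <= -(threshold_nm_min - fp_eps)
    labels[lateral] = np.where(moving_plus[lateral], "run_plus", "paused")
    labels[~lateral] = np.where(moving_minus[~lateral], "tip_track", "tip_paused")

    # moving segments below the resolution window merge into the pause state
    for start, stop, lab in _runs_of(labels):
        if lab in ("run_plus", "tip_track") and stop - start < min_moving_frames:
            labels[start:stop] = "paused" if lab == "run_plus" else "tip_paused"

    segments = [
        Segment(start, stop, lab, _segment_velocity(x, frame_interval, start, stop))
        for start, stop, lab in _runs_of(labels)
    ]
    return Segmentation(
        segments=segments,
        threshold_nm_min=threshold_nm_min,
        window_frames=window_frames,
        end_on_frame=end_on,
        n_frames=n,
    )
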