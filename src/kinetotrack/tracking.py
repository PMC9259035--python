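"""Extract kinetochore tracks and plus-end positions from kymograph images.

The published analysis traced kymograph lines by hand in Fiji; here the same
readout is automated.  The kinetochore is followed frame by frame with an
intensity-weighted centroid inside a search window around its previous
position; frames whose local signal falls below a visibility threshold
(fluorophore blinking, noise dips) are flagged invisible and bridged by
linear interpolation.  The microtubule plus end is read per frame as the
half-maximum crossing of the (blurred) lattice intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .render import KymographImage

__all__ = ["Track", "TrackLostError", "extract_track", "extract_plus_end"]


class TrackLostError(RuntimeError):
    """Raised when a track cannot be followed across too long a gap."""

    def __init__(self, frame: int, max_gap: int):
        self.frame = frame
        super().__init__(
            f"track lost at frame {frame}: invisible for more than {max_gap} frames"
        )


@dataclass
class Track:
    """A single-particle track on the kymograph frame grid.

    ``positions_um`` is defined at every frame; frames where the particle was
    not directly visible carry interpolated positions and ``visible=False``.
    """

    trajectory_id: str | int
    frames: np.ndarray          # 0-based, strictly increasing
    positions_um: np.ndarray
    visible: np.ndarray         # bool per frame
    qc_excluded: bool = False   # crossed/bundled-microtubule exclusion hook

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (len(self.frames) == len(self.positions_um) == len(self.visible)):
            raise ValueError("frames, positions and visibility must align")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trajectory_id": self.trajectory_id,
            "frame": self.frames,
            "position_um": self.positions_um,
            "visible": self.visible,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Track":
        df = pd.read_csv(path).sort_values("frame")
        return cls(
            trajectory_id=df["trajectory_id"].iloc[0],
            frames=df["frame"].to_numpy(int),
            positions_um=df["position_um"].to_numpy(float),
            visible=(df["visible"].to_numpy(bool)
                     if "visible" in df else np.ones(len(df), dtype=bool)),
        )


def _robust_background(img: np.ndarray) -> tuple[float, float]:
    """Median background level and a MAD-based noise scale."""
    bg = float(np.median(img))
    sigma = 1.4826 * float(np.median(np.abs(img - bg)))
    return bg, max(sigma, 1e-6)


def _interpolate_gaps(pos: np.ndarray, visible: np.ndarray) -> np.ndarray:
    out = pos.copy()
    idx = np.nonzero(visible)[0]
    if idx.size == 0:
        raise ValueError("particle never visible; nothing to track")
    missing = ~visible
    out[missing] = np.interp(np.nonzero(missing)[0], idx, pos[idx])
    return out


def extract_track(
    kymo: KymographImage,
    channel: str = "kinetochore",
    start_hint: float | None = None,
    search_halfwidth_px: int = 6,
    max_gap: int = 12,
    visibility_nsigma: float = 4.0,
    trajectory_id: str | int = 0,
) -> Track:
    """Follow a point emitter through a kymograph channel.

    Parameters
    ----------
    start_hint:
        Starting distance pixel; defaults to the brightest pixel of the first
        visible frame.
    search_halfwidth_px:
        Centroid window half-width around the previous position.
    max_gap:
        Maximum number of consecutive invisible frames before the track is
        declared lost (:class:`TrackLostError`).
    """
    img = kymo.channel(channel)
    n_px, n_t = img.shape
    bg, sigma = _robust_background(img)
    if start_hint is not None and not 0 <= start_hint < n_px:
        raise ValueError(f"start_hint {start_hint} outside image (0..{n_px - 1})")

    smoothed0 = gaussian_filter1d(img, 1.0, axis=0)
    if start_hint is None:
        # first frame with a clear spot anywhere
        start_frame = None
        for t in range(n_t):
            if smoothed0[:, t].max() > bg + visibility_nsigma * sigma:
                start_hint = float(np.argmax(smoothed0[:, t]))
                start_frame = t
                break
        if start_frame is None:
            raise ValueError(f"no visible particle in channel {channel!r}")
        if start_frame > max_gap:
            raise TrackLostError(0, max_gap)

    rows = np.arange(n_px)
    positions = np.full(n_t, np.nan)
    visible = np.zeros(n_t, dtype=bool)
    prev = float(start_hint)
    gap = 0
    for t in range(n_t):
        lo = max(0, int(round(prev)) - search_halfwidth_px)
        hi = min(n_px, int(round(prev)) + search_halfwidth_px + 1)
        window = img[lo:hi, t] - bg
        peak = float(window.max()) if window.size else 0.0
        if peak > visibility_nsigma * sigma:
            w = np.clip(window, 0.0, None)
            prev = float(np.sum(rows[lo:hi] * w) / np.sum(w))
            positions[t] = prev
            visible[t] = True
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                raise TrackLostError(t, max_gap)
    positions = _interpolate_gaps(positions, visible)
    return Track(
        trajectory_id=trajectory_id,
        frames=np.arange(n_t),
        positions_um=positions * kymo.calibration.pixel_um,
        visible=visible,
    )


def extract_plus_end(
    kymo: KymographImage,
    channel: str = "microtubule",
    visibility_nsigma: float = 4.0,
) -> np.ndarray:
    """Per-frame plus-end position (µm) from the lattice channel.

    For each frame the lattice intensity level is estimated near the seed and
    the plus end read as the half-maximum crossing of the smoothed profile
    (sub-pixel by linear interpolation).  Frames where the channel is dark
    (blinking) are bridged by linear interpolation in time.
    """
    img = kymo.channel(channel)
    n_px, n_t = img.shape
    # the rows just below the image top are empty by construction (render
    # margin), so they estimate background even when the lattice covers most
    # of the field; the median would saturate at the lattice level instead
    top = img[max(n_px - max(n_px // 8, 4), 0):]
    bg, sigma = _robust_background(top)
    sm = gaussian_filter1d(img, 1.0, axis=0)
    tips = np.full(n_t, np.nan)
    visible = np.zeros(n_t, dtype=bool)
    for t in range(n_t):
        col = sm[:, t]
        level = float(np.mean(col[1:6])) if n_px > 6 else float(col.max())
        if level - bg < visibility_nsigma * sigma:
            continue
        half = bg + 0.5 * (level - bg)
        above = np.nonzero(col >= half)[0]
        if above.size == 0:
            continue
        i = int(above[-1])
        if i + 1 < n_px and col[i] > col[i + 1]:
            frac = (col[i] - half) / (col[i] - col[i + 1])
            tip = i + float(np.clip(frac, 0.0, 1.0))
        else:
            tip = float(i)
        tips[t] = tip
        visible[t] = True
    if not visible.any():
        raise ValueError(f"microtubule never visible in channel {channel!r}")
    tips = _interpolate_gaps(tips, visible)
    return tips * kymo.calibration.pixel_um
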