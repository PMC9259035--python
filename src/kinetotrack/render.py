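"""Render ground-truth trajectories into noisy multi-channel kymographs.

A kymograph is stored as ``data[channel, distance_pixel, time_pixel]`` with
the seed (minus end) at distance pixel 0, mirroring the usual display of
these experiments (distance on the vertical axis, time on the horizontal).
The microtubule channel is a line of emitters from the seed to the plus end;
the kinetochore channel is a single point emitter convolved with a 1-D
Gaussian PSF.  Fluorophore blinking is an exponential on/off telegraph
applied per channel (by default only the red/microtubule channel blinks, as
red fluorescent protein tags do), and shot noise is Poisson by default.

The module also synthesizes in-vivo spindle line-scan profiles (bilobed vs
declustered kinetochore clustering phenotypes) for the phenotype classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import Trajectory, PIXEL_UM

__all__ = [
    "ImagingConfig",
    "KymographImage",
    "SpindleProfile",
    "render_kymograph",
    "render_spindle_profile",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Physical calibration and noise model of the synthetic microscope.

    ``photon_rate`` is the expected photon count per emitter per frame
    (the microtubule lattice contributes one emitter per distance pixel);
    ``background`` is the mean background count per pixel per frame.
    ``blink_off_mean = 0`` disables blinking entirely.
    """

    pixel_size_nm: float = 72.2
    frame_interval: float = 5.0       # s
    duration: float = 1800.0          # s
    psf_sigma_nm: float = 150.0
    photon_rate: float = 200.0
    background: float = 10.0
    noise_model: str = "poisson"      # poisson | gaussian | none
    blink_on_mean: float = 20.0       # s
    blink_off_mean: float = 10.0      # s; 0 disables blinking
    blink_channels: tuple[str, ...] = ("microtubule",)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size_nm and frame_interval must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be non-negative")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of frame_interval")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.blink_on_mean <= 0 or self.blink_off_mean < 0:
            raise ValueError("blink_on_mean must be > 0 and blink_off_mean >= 0")

    @property
    def pixel_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    @property
    def blink_duty_cycle(self) -> float:
        if self.blink_off_mean == 0:
            return 1.0
        return self.blink_on_mean / (self.blink_on_mean + self.blink_off_mean)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blink_channels"] = list(self.blink_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        d = dict(d)
        d["blink_channels"] = tuple(d.get("blink_channels", ()))
        return cls(**d)


@dataclass
class KymographImage:
    """Multi-channel distance x time intensity raster with calibration."""

    data: np.ndarray                  # [channel, distance_px, time_px]
    channels: tuple[str, ...]
    calibration: ImagingConfig
    origin: int = 0                   # seed position, distance pixel 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be [channel, distance, time] matching channels")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {', '.join(self.channels)}"
            ) from None

    def to_tiff(self, path: str | Path) -> None:
        info = {
            "channels": list(self.channels),
            "calibration": self.calibration.to_dict(),
            "origin": self.origin,
        }
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            imagej=True,
            metadata={"axes": "CYX", "Info": json.dumps(info)},
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "KymographImage":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(float)
            meta = tif.imagej_metadata or {}
        info = json.loads(meta.get("Info", "{}"))
        if data.ndim == 2:
            data = data[None]
        return cls(
            data=data,
            channels=tuple(info.get("channels", [f"ch{i}" for i in range(data.shape[0])])),
            calibration=ImagingConfig.from_dict(info["calibration"]),
            origin=int(info.get("origin", 0)),
        )


def _telegraph(rng: np.random.Generator, n_frames: int, frame_interval: float,
               on_mean: float, off_mean: float) -> np.ndarray:
    """On/off blinking state sampled at frame instants (stationary start)."""
    if off_mean == 0:
        return np.ones(n_frames, dtype=bool)
    duty = on_mean / (on_mean + off_mean)
    total = n_frames * frame_interval
    t = 0.0
    on = rng.random() < duty
    edges = [0.0]
    states = [on]
    while t < total:
        t += float(rng.exponential(on_mean if on else off_mean))
        on = not on
        edges.append(t)
        states.append(on)
    times = np.arange(n_frames) * frame_interval
    idx = np.searchsorted(edges, times, side="right") - 1
    return np.array(states, dtype=bool)[idx]


def _psf_kernel(sigma_px: float) -> np.ndarray:
    if sigma_px == 0:
        return np.array([1.0])
    half = max(1, int(math.ceil(4 * sigma_px)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    return k / k.sum()


def _apply_noise(expected: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(expected).astype(float)
    if model == "gaussian":
        return expected + rng.normal(0.0, np.sqrt(np.maximum(expected, 1.0)))
    return expected.copy()


def render_kymograph(
    traj: Trajectory,
    cfg: ImagingConfig,
    rng,
    channels: tuple[str, ...] = ("microtubule", "kinetochore"),
    n_distance_px: int | None = None,
) -> KymographImage:
    """Render one trajectory into a noisy two-channel kymograph.

    The kinetochore channel places ``cfg.photon_rate`` expected photons in a
    discrete Gaussian PSF profile centred on the kinetochore each frame (so
    summed intensity per visible frame is exactly conserved); the microtubule
    channel fills pixels up to the plus end (fractional coverage at the tip)
    and is then blurred by the same PSF.  Channels listed in
    ``cfg.blink_channels`` are switched by an exponential on/off telegraph.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_t = traj.n_frames
    if n_t != cfg.n_frames or abs(traj.frame_interval - cfg.frame_interval) > 1e-9:
        raise ValueError(
            f"trajectory grid ({n_t} frames @ {traj.frame_interval}s) does not "
            f"match imaging config ({cfg.n_frames} frames @ {cfg.frame_interval}s)"
        )
    px = cfg.pixel_um
    if n_distance_px is None:
        extent = max(float(np.max(traj.mt_plus_end)), float(np.max(traj.kt_position)))
        n_distance_px = int(math.ceil(extent / px)) + int(math.ceil(8 * cfg.psf_sigma_px)) + 4

    data = np.zeros((len(channels), n_distance_px, n_t), dtype=float)
    kernel = _psf_kernel(cfg.psf_sigma_px)
    half = len(kernel) // 2
    rows = np.arange(n_distance_px)

    for ci, name in enumerate(channels):
        if name == "kinetochore":
            centers = traj.kt_position / px
            for ti in range(n_t):
                c = centers[ti]
                lo = max(0, int(math.floor(c)) - half - 2)
                hi = min(n_distance_px, int(math.ceil(c)) + half + 3)
                w = np.exp(-0.5 * ((rows[lo:hi] - c) / max(cfg.psf_sigma_px, 1e-6)) ** 2)
                s = w.sum()
                if s > 0:
                    data[ci, lo:hi, ti] = cfg.photon_rate * w / s
        elif name == "microtubule":
            tips = traj.mt_plus_end / px
            # pixel i spans [i-0.5, i+0.5): half-max edge sits at the tip
            cover = np.clip(tips[None, :] - rows[:, None] + 0.5, 0.0, 1.0)
            prof = cfg.photon_rate * cover
            # blur along the distance axis
            from scipy.ndimage import convolve1d
            data[ci] = convolve1d(prof, kernel, axis=0, mode="constant")
        elif name == "seed":
            w = np.exp(-0.5 * (rows / max(cfg.psf_sigma_px, 1e-6)) ** 2)
            data[ci] = (cfg.photon_rate * w / max(w.sum(), 1e-12))[:, None] * np.ones(n_t)
        else:
            raise ValueError(f"unknown channel {name!r}")

        if name in cfg.blink_channels and cfg.blink_off_mean > 0:
            vis = _telegraph(rng, n_t, cfg.frame_interval,
                             cfg.blink_on_mean, cfg.blink_off_mean)
            data[ci] *= vis[None, :]

    expected = data + cfg.background
    noisy = _apply_noise(expected, cfg.noise_model, rng)
    return KymographImage(data=noisy, channels=tuple(channels), calibration=cfg)


# ---------------------------------------------------------------------------
# In vivo spindle line-scan profiles
# ---------------------------------------------------------------------------

@dataclass
class SpindleProfile:
    """A 1-D kinetochore-fluorescence line scan along the spindle axis."""

    position_um: np.ndarray
    intensity: np.ndarray
    spindle_length: float
    phenotype: str | None = None      # ground-truth label for synthetic data

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"position_um": self.position_um,
                      "intensity": self.intensity}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, phenotype: str | None = None) -> "SpindleProfile":
        df = pd.read_csv(path)
        pos = df["position_um"].to_numpy(float)
        return cls(pos, df["intensity"].to_numpy(float),
                   spindle_length=float(pos[-1] - pos[0]), phenotype=phenotype)


def render_spindle_profile(
    phenotype: str,
    spindle_length: float,
    cfg: ImagingConfig,
    rng,
    declustered_variant: str | None = None,
) -> SpindleProfile:
    """Synthesize a metaphase spindle line scan for a given phenotype.

    ``bilobed`` places two kinetochore clusters near the spindle poles.
    ``declustered`` draws either >= 3 separated foci at random axial
    positions or one elongated plateau spanning the spindle
    (``declustered_variant`` in {"multi", "plateau"}; random if None).
    Only spindles 2-3 µm long are rendered, mirroring the inclusion window
    used when scoring the phenotype in cells.
    """
    if not 2.0 <= spindle_length <= 3.0:
        raise ValueError(
            f"spindle_length {spindle_length:.2f} µm outside the 2-3 µm scoring window"
        )
    if phenotype not in ("bilobed", "declustered"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    px = cfg.pixel_um
    # the scan spans exactly the spindle axis, so its length is recoverable
    # from the positions alone (CSV round trip)
    pos = np.linspace(0.0, spindle_length, int(round(spindle_length / px)) + 1)
    sigma = max(cfg.psf_sigma_nm / 1000.0, 0.08)
    expected = np.zeros_like(pos)

    def add_spot(center: float, amplitude: float) -> None:
        nonlocal expected
        expected = expected + amplitude * np.exp(-0.5 * ((pos - center) / sigma) ** 2)

    if phenotype == "bilobed":
        offset = rng.uniform(0.3, 0.5)
        for c in (offset, spindle_length - offset):
            add_spot(c, cfg.photon_rate * rng.uniform(0.8, 1.2))
    else:
        variant = declustered_variant or ("multi" if rng.random() < 0.5 else "plateau")
        if variant == "multi":
            lo, hi = 0.3, spindle_length - 0.3
            # only as many foci as the spindle can separate at >= 0.6 µm
            max_k = max(3, int((hi - lo - 0.3) / 0.6) + 1)
            k = min(int(rng.integers(3, 6)), max_k)
            centers = None
            for _ in range(1000):
                draw = np.sort(rng.uniform(lo, hi, size=k))
                if k <= 1 or np.min(np.diff(draw)) >= 0.6:
                    centers = draw
                    break
            if centers is None:   # rejection infeasible: jittered even spacing
                centers = np.linspace(lo, hi, k) + rng.uniform(-0.05, 0.05, k)
            for c in centers:
                add_spot(float(c), cfg.photon_rate * rng.uniform(0.7, 1.3))
        elif variant == "plateau":
            inside = (pos >= 0.2) & (pos <= spindle_length - 0.2)
            plateau = inside.astype(float)
            from scipy.ndimage import gaussian_filter1d
            expected = cfg.photon_rate * 0.8 * gaussian_filter1d(plateau, sigma / px)
        else:
            raise ValueError(f"unknown declustered variant {variant!r}")

    expected = expected + cfg.background
    intensity = _apply_noise(expected, cfg.noise_model, rng)
    return SpindleProfile(pos, intensity, spindle_length, phenotype=phenotype)
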