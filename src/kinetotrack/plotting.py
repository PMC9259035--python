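"""Minimal visualization helpers (kymographs and spindle line scans)."""

from __future__ import annotations

import numpy as np

from .render import KymographImage, SpindleProfile

__all__ = ["plot_kymograph", "plot_spindle_profile"]


def plot_kymograph(kymo: KymographImage, ax=None, channel_colors=("Reds", "Greens", "Blues")):
    """Show a multi-channel kymograph (distance vertical, time horizontal)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    cal = kymo.calibration
    extent = (0, cal.duration / 60.0, 0, kymo.data.shape[1] * cal.pixel_um)
    for ci in range(kymo.data.shape[0]):
        img = kymo.data[ci]
        ax.imshow(img, origin="lower", aspect="auto", extent=extent,
                  cmap=channel_colors[ci % len(channel_colors)],
                  alpha=1.0 if ci == 0 else 0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("distance from seed (µm)")
    return ax


def plot_spindle_profile(profile: SpindleProfile, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.position_um, profile.intensity, lw=1)
    label = profile.phenotype or "line scan"
    ax.set_title(f"{label} (L = {profile.spindle_length:.2f} µm)")
    ax.set_xlabel("position along spindle axis (µm)")
    ax.set_ylabel("intensity (counts)")
    return ax
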