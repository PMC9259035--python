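"""Group statistics and histogram utilities for cohort reports."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["GroupComparison", "kruskal_wallis", "make_histogram"]


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    test_name: str = "kruskal-wallis"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray]) -> GroupComparison:
    """Rank-based k-sample test (Kruskal–Wallis H with tie correction).

    The degenerate all-tied case (every pooled value identical), where the
    tie correction removes all rank variance, is reported as H = 0, p = 1.
    """
    if isinstance(groups, dict):
        labels = tuple(groups)
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
        labels = tuple(f"group{i}" for i in range(len(samples)))
    if len(samples) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return GroupComparison(labels, 0.0, 1.0)
    h, p = sstats.kruskal(*samples)
    return GroupComparison(labels, float(h), float(p))


def make_histogram(values, bin_width: float = 0.2) -> pd.DataFrame:
    """Counts in half-open bins ``[k*w, (k+1)*w)`` (edge values go up).

    Returns a DataFrame with columns ``bin_left``, ``bin_right``, ``count``;
    empty input yields an empty histogram.  Counts always sum to ``len(values)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
    # nudge keeps values sitting exactly on an edge in the upper bin
    idx = np.floor(values / bin_width + 1e-9).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    ks = np.arange(lo, hi + 1)
    return pd.DataFrame({
        "bin_left": ks * bin_width,
        "bin_right": (ks + 1) * bin_width,
        "count": counts,
    })
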