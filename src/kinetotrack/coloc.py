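"""Two-channel track colocalization with a blinking reference fluorophore.

Pairs of kinetochore-protein tracks are scored into three categories:
``always`` colocalized, ``partially`` colocalized (the reference signal
appears alone, then the query signal appears on it and stays for the rest of
the movie), or ``never``.  Because red fluorescent protein tags blink,
scoring is restricted to frames where the reference is directly visible;
blinking gaps therefore cannot turn a truly colocalized pair into "never".
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .tracking import Track

__all__ = ["ColocCategory", "score_colocalization"]

#: default colocalization distance: one kymograph pixel, in µm
DEFAULT_DIST_THRESH_UM = 0.0722


class ColocCategory(str, Enum):
    ALWAYS = "always"
    PARTIALLY = "partially"
    NEVER = "never"


def score_colocalization(
    ref: Track,
    query: Track,
    dist_thresh_um: float = DEFAULT_DIST_THRESH_UM,
    sustain_fraction: float = 0.9,
    min_suffix_frames: int = 5,
) -> ColocCategory:
    """Score a track pair as always / partially / never colocalized.

    Evaluation is restricted to frames where ``ref`` is visible; a frame is
    colocalized when the two positions are within ``dist_thresh_um`` (and the
    query position is defined).  ``always`` requires colocalization on at
    least ``sustain_fraction`` of evaluated frames (tolerating localization
    noise); ``partially`` requires a mostly-apart prefix followed by a
    sustained (>= ``sustain_fraction``) colocalized suffix reaching the end of
    the movie.  Colocalization that ends before the movie does maps to
    ``never``.
    """
    if dist_thresh_um <= 0:
        raise ValueError("dist_thresh_um must be positive")
    if ref.n_frames != query.n_frames or np.any(ref.frames != query.frames):
        raise ValueError("ref and query tracks must share the same frame grid")

    eval_mask = np.asarray(ref.visible, dtype=bool)
    if not eval_mask.any():
        raise ValueError("reference track is never visible; nothing to score")
    dist = np.abs(ref.positions_um - query.positions_um)
    coloc = (dist <= dist_thresh_um) & ~np.isnan(dist)
    c = coloc[eval_mask].astype(float)
    m = len(c)

    if c.mean() >= sustain_fraction:
        return ColocCategory.ALWAYS

    # earliest evaluated frame from which colocalization is sustained to the end
    suffix_means = np.cumsum(c[::-1])[::-1] / np.arange(m, 0, -1)
    candidates = np.nonzero(suffix_means >= sustain_fraction)[0]
    for k in candidates:
        if m - k < min_suffix_frames or k == 0:
            continue
        prefix = c[:k]
        if prefix.mean() <= 1.0 - sustain_fraction:
            return ColocCategory.PARTIALLY
        break
    return ColocCategory.NEVER
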