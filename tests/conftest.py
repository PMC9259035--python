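import numpy as np
import pytest

from kinetotrack import ImagingConfig, Trajectory, make_preset


@pytest.fixture(scope="session")
def wt():
    return make_preset("WT")


@pytest.fixture(scope="session")
def kip3_null():
    return make_preset("kip3_null")


@pytest.fixture
def clean_imaging():
    """Noise-free, blink-free imaging at the standard calibration."""
    return ImagingConfig(noise_model="none", blink_off_mean=0.0, duration=1800.0)


@pytest.fixture
def short_imaging():
    """Default (Poisson, blinking MT channel) imaging for short 5-min movies."""
    return ImagingConfig(duration=300.0)


@pytest.fixture
def trajectory_factory():
    """Build a ground-truth Trajectory from explicit position arrays."""

    def build(kt_position, mt_plus_end=None, frame_interval=5.0,
              state=None, attachment=None, motile=True):
        kt_position = np.asarray(kt_position, dtype=float)
        n = len(kt_position)
        times = np.arange(n) * frame_interval
        if mt_plus_end is None:
            mt_plus_end = np.full(n, kt_position.max() + 5.0)
        mt_plus_end = np.asarray(mt_plus_end, dtype=float)
        if attachment is None:
            attachment = np.where(mt_plus_end - kt_position <= 0.0722,
                                  "end_on", "lateral")
        else:
            attachment = np.asarray(attachment, dtype="<U7")
        if state is None:
            state = np.where(attachment == "lateral", "lateral_pause", "tip_pause")
        return Trajectory(times=times, kt_position=kt_position,
                          mt_plus_end=mt_plus_end,
                          state=np.asarray(state, dtype="<U13"),
                          attachment=attachment, motile=motile)

    return build
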