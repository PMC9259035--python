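import math

import numpy as np
import pytest

from kinetotrack import (
    ImagingConfig,
    KymographImage,
    render_kymograph,
    render_spindle_profile,
)
from kinetotrack.render import _telegraph


def centroid_um(kymo, channel, t):
    col = kymo.channel(channel)[:, t]
    rows = np.arange(len(col))
    return float(np.sum(rows * col) / col.sum()) * kymo.calibration.pixel_um


class TestKymograph:
    def test_static_noiseless_emitter_is_constant_and_centred(
            self, trajectory_factory):
        cfg = ImagingConfig(noise_model="none", blink_off_mean=0.0,
                            background=0.0, duration=300.0)
        traj = trajectory_factory(np.full(60, 2.0), np.full(60, 6.0))
        kymo = render_kymograph(traj, cfg, 0)
        kt = kymo.channel("kinetochore")
        # every time column identical
        assert np.allclose(kt, kt[:, [0]])
        assert centroid_um(kymo, "kinetochore", 0) == pytest.approx(2.0, abs=0.01)

    def test_energy_conservation_without_noise(self, trajectory_factory):
        cfg = ImagingConfig(noise_model="none", blink_off_mean=0.0,
                            background=0.0, duration=300.0)
        x = np.linspace(1.0, 3.0, 60)
        kymo = render_kymograph(trajectory_factory(x), cfg, 0)
        sums = kymo.channel("kinetochore").sum(axis=0)
        np.testing.assert_allclose(sums, cfg.photon_rate, rtol=1e-9)

    def test_no_blinking_means_always_visible(self, trajectory_factory):
        cfg = ImagingConfig(noise_model="none", blink_off_mean=0.0,
                            background=0.0, duration=300.0,
                            blink_channels=("kinetochore",))
        kymo = render_kymograph(trajectory_factory(np.full(60, 2.0)), cfg, 0)
        assert np.all(kymo.channel("kinetochore").sum(axis=0) > 0)

    def test_blinking_switches_whole_frames_off(self, trajectory_factory):
        cfg = ImagingConfig(noise_model="none", background=0.0, duration=1800.0,
                            blink_on_mean=20.0, blink_off_mean=10.0,
                            blink_channels=("kinetochore",))
        kymo = render_kymograph(trajectory_factory(np.full(360, 2.0)), cfg, 5)
        sums = kymo.channel("kinetochore").sum(axis=0)
        on = sums > 0
        assert 0 < on.sum() < len(on)
        np.testing.assert_allclose(sums[on], cfg.photon_rate, rtol=1e-9)

    def test_centroid_rmse_under_poisson_noise_below_half_pixel(
            self, trajectory_factory):
        from kinetotrack import extract_track
        cfg = ImagingConfig(noise_model="poisson", blink_off_mean=0.0,
                            duration=300.0)
        x = 1.0 + np.arange(60) * (0.56 / 60.0) * 5.0
        errs = []
        for seed in range(20):
            kymo = render_kymograph(trajectory_factory(x), cfg, seed)
            track = extract_track(kymo)
            errs.append(track.positions_um - x)
        rmse_px = np.sqrt(np.mean(np.square(errs))) / cfg.pixel_um
        assert rmse_px < 0.5

    def test_grid_mismatch_rejected(self, trajectory_factory):
        cfg = ImagingConfig(duration=300.0)
        with pytest.raises(ValueError, match="does not match"):
            render_kymograph(trajectory_factory(np.full(10, 1.0)), cfg, 0)

    def test_tiff_round_trip(self, trajectory_factory, tmp_path):
        cfg = ImagingConfig(duration=300.0)
        kymo = render_kymograph(trajectory_factory(np.full(60, 2.0)), cfg, 0)
        path = tmp_path / "kymo.tif"
        kymo.to_tiff(path)
        back = KymographImage.from_tiff(path)
        assert back.channels == kymo.channels
        assert back.calibration == kymo.calibration
        np.testing.assert_allclose(back.data, kymo.data, rtol=1e-6)


class TestBlinkTelegraph:
    def test_duty_cycle_converges_to_on_fraction(self):
        on_mean, off_mean = 20.0, 10.0
        rng = np.random.default_rng(0)
        fracs = [
            _telegraph(rng, 200, 5.0, on_mean, off_mean).mean()
            for _ in range(150)
        ]
        duty = on_mean / (on_mean + off_mean)
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - duty) < 3 * se


class TestSpindleProfiles:
    def test_bilobed_noiseless_has_exactly_two_halfmax_maxima(self):
        cfg = ImagingConfig(noise_model="none", background=0.0)
        prof = render_spindle_profile("bilobed", 2.5, cfg, 1)
        y = prof.intensity
        half = y.max() / 2
        maxima = [i for i in range(1, len(y) - 1)
                  if y[i] > half and y[i] >= y[i - 1] and y[i] > y[i + 1]]
        assert len(maxima) == 2

    def test_declustered_plateau_has_no_two_separated_peaks(self):
        cfg = ImagingConfig(noise_model="none", background=0.0)
        prof = render_spindle_profile("declustered", 2.5, cfg, 1,
                                      declustered_variant="plateau")
        y = prof.intensity
        half = y.max() / 2
        strict_maxima = [i for i in range(1, len(y) - 1)
                         if y[i] > half and y[i] > y[i - 1] and y[i] > y[i + 1]]
        assert len(strict_maxima) <= 1

    def test_multi_spot_variant_has_three_or_more_foci(self):
        from kinetotrack import classify_spindle
        cfg = ImagingConfig(noise_model="none", background=0.0)
        for seed in range(5):
            prof = render_spindle_profile("declustered", 3.0, cfg, seed,
                                          declustered_variant="multi")
            call = classify_spindle(prof.position_um, prof.intensity)
            assert call.value == "declustered"
            assert call.n_peaks >= 3

    def test_out_of_window_spindle_rejected(self):
        cfg = ImagingConfig()
        with pytest.raises(ValueError, match="2-3"):
            render_spindle_profile("bilobed", 3.5, cfg, 0)
        with pytest.raises(ValueError, match="phenotype"):
            render_spindle_profile("weird", 2.5, cfg, 0)


def test_imaging_config_validation():
    with pytest.raises(ValueError):
        ImagingConfig(duration=1003.0)          # not a multiple of 5 s
    with pytest.raises(ValueError):
        ImagingConfig(noise_model="salt")
    with pytest.raises(ValueError):
        ImagingConfig(pixel_size_nm=0.0)
    assert ImagingConfig(blink_off_mean=0.0).blink_duty_cycle == 1.0
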