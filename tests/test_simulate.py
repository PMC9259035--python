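import math

import numpy as np
import pytest

from kinetotrack import (
    PIXEL_UM,
    TrajectorySet,
    make_preset,
    simulate_cohort,
    simulate_kinetochore,
    simulate_microtubule,
    simulate_rescue,
)


def lateral_only(preset):
    """Variant that never converts: long microtubule, no catastrophe."""
    return preset.replace(f_cat=0.0, L0_range=(60.0, 60.0),
                          x0_fraction_range=(0.01, 0.01), p_motile=1.0)


class TestMicrotubule:
    def test_deterministic_growth(self, wt):
        p = wt.replace(f_cat=0.0, v_growth=1.0)
        mt = simulate_microtubule(p, 300, 5, 0, L0=0.0)
        assert mt.position_at(300.0) == pytest.approx(5.0)
        np.testing.assert_allclose(mt.position, mt.times / 60.0)
        assert set(mt.phase) == {"growth"}

    def test_zero_growth_zero_catastrophe_constant_length(self, wt):
        p = wt.replace(f_cat=0.0, v_growth=0.0)
        mt = simulate_microtubule(p, 300, 5, 0, L0=3.0)
        np.testing.assert_allclose(mt.position, 3.0)

    def test_length_never_below_seed(self, wt):
        p = wt.replace(f_cat=6.0, v_depol_free=5.0)
        for seed in range(5):
            mt = simulate_microtubule(p, 1800, 5, seed, L0=2.0)
            assert np.all(mt.position >= 0.0)

    def test_catastrophe_count_matches_poisson_expectation(self, wt):
        # one catastrophe max (no rescue): E[N] = P(T_cat < T) = 1 - exp(-f*T)
        f_cat, minutes, n = 0.1, 10.0, 4000
        p = wt.replace(f_cat=f_cat)
        rng = np.random.default_rng(42)
        counts = np.array([
            simulate_microtubule(p, minutes * 60, 5, rng).n_catastrophes
            for _ in range(n)
        ])
        expected = 1.0 - math.exp(-f_cat * minutes)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(counts.mean() - expected) < 3 * se

    def test_invalid_inputs_rejected(self, wt):
        with pytest.raises(ValueError):
            simulate_microtubule(wt, -5, 5, 0)
        with pytest.raises(ValueError):
            simulate_microtubule(wt, 300, 0, 0)


class TestKinetochore:
    def test_immobile_limit_holds_position_while_lateral(self, wt):
        p = wt.replace(p_motile=0.0, f_cat=0.0)
        mt = simulate_microtubule(p, 1800, 5, 3)
        traj = simulate_kinetochore(p, mt, 3)
        assert not traj.motile
        lateral = traj.attachment == "lateral"
        assert np.allclose(traj.kt_position[lateral], traj.kt_position[0])

    def test_vanishing_pause_gives_one_uninterrupted_run(self, wt):
        p = lateral_only(wt).replace(t_pause_mean=1e-9)
        mt = simulate_microtubule(p, 1800, 5, 7, L0=60.0)
        traj = simulate_kinetochore(p, mt, 7)
        lateral = traj.attachment == "lateral"
        v = np.diff(traj.kt_position[lateral]) / 5.0 * 60.0
        np.testing.assert_allclose(v, p.v_run, rtol=1e-6)

    def test_two_state_occupancy_matches_closed_form(self, wt):
        # pooled over >= 10,000 lateral frames; SE from per-trajectory fractions
        p = lateral_only(wt)
        ts = simulate_cohort(p, 40, 1800, 5, 11)
        fracs = np.array([
            np.mean(tr.state[tr.attachment == "lateral"] == "lateral_run")
            for tr in ts
        ])
        assert sum(tr.n_frames for tr in ts) >= 10_000
        expected = p.lateral_moving_fraction
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se

    def test_longer_pauses_strictly_slow_gross_transport(self, wt):
        speeds = []
        for t_pause in (60.0, 180.0, 540.0):
            p = lateral_only(wt).replace(t_pause_mean=t_pause)
            ts = simulate_cohort(p, 30, 1800, 5, 123)  # paired seeds
            gross = [(tr.kt_position[-1] - tr.kt_position[0]) / 30.0 for tr in ts]
            speeds.append(np.mean(gross))
        assert speeds[0] > speeds[1] > speeds[2]


class TestTrajectoryInvariants:
    @pytest.mark.parametrize("name", ["WT", "kip3_null", "kip3_dT_LZ"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_model_invariants(self, name, seed):
        ts = simulate_cohort(make_preset(name), 16, 1800, 5, seed)
        for tr in ts:
            # never above the plus end (one lattice-step tolerance)
            assert np.all(tr.kt_position <= tr.mt_plus_end + PIXEL_UM + 1e-9)
            # lateral -> end_on at most once, irreversible
            end_on = tr.attachment == "end_on"
            switches = np.diff(end_on.astype(int))
            assert np.all(switches >= 0) and switches.sum() <= 1
            if end_on.any():
                # rides the tip, which never regrows
                np.testing.assert_allclose(
                    tr.kt_position[end_on], tr.mt_plus_end[end_on])
                assert np.all(np.diff(tr.mt_plus_end[end_on]) <= 1e-9)
                # tip-coupled depolymerization never beats the tip-tracking speed
                dv = -np.diff(tr.mt_plus_end[end_on]) / 5.0 * 60.0
                assert np.all(dv <= make_preset(name).v_tip_track + 1e-6)
            # never detaches: position defined everywhere
            assert np.all(np.isfinite(tr.kt_position))

    def test_states_are_consistent_with_attachment(self, wt):
        ts = simulate_cohort(wt, 8, 1800, 5, 5)
        for tr in ts:
            lateral = tr.attachment == "lateral"
            assert set(np.unique(tr.state[lateral])) <= {"lateral_run", "lateral_pause"}
            assert set(np.unique(tr.state[~lateral])) <= {"tip_move", "tip_pause"}


class TestCohort:
    def test_seed_determinism_and_independence(self, wt):
        a = simulate_cohort(wt, 6, 600, 5, 99)
        b = simulate_cohort(wt, 6, 600, 5, 99)
        c = simulate_cohort(wt, 6, 600, 5, 100)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.kt_position, y.kt_position)
            np.testing.assert_array_equal(x.state, y.state)
        assert any(not np.array_equal(x.kt_position, y.kt_position)
                   for x, y in zip(a, c))

    def test_cohort_shape_matches_movie(self, wt):
        ts = simulate_cohort(wt, 128, 1800, 5, 1)
        assert len(ts) == 128
        assert all(tr.n_frames == 360 for tr in ts)

    def test_bad_cohort_size_rejected(self, wt):
        with pytest.raises(ValueError):
            simulate_cohort(wt, 0, 1800, 5, 1)

    def test_csv_round_trip(self, wt, tmp_path):
        ts = simulate_cohort(wt, 4, 300, 5, 8)
        path = tmp_path / "cohort.csv"
        ts.to_csv(path)
        back = TrajectorySet.from_csv(path, wt)
        assert len(back) == len(ts)
        for x, y in zip(ts, back):
            np.testing.assert_allclose(x.kt_position, y.kt_position)
            np.testing.assert_array_equal(x.state, y.state)
            np.testing.assert_array_equal(x.attachment, y.attachment)
            assert x.motile == y.motile and x.rng_seed == y.rng_seed


class TestRescue:
    def test_rescue_probability_limits(self, wt, kip3_null):
        never = simulate_rescue(kip3_null, wt, 600, 0.0, 20, 4,
                                all_immobile=True)
        assert not any(tr.rescued for tr in never)
        for tr in never:
            lateral = tr.attachment == "lateral"
            assert np.allclose(tr.kt_position[lateral], tr.kt_position[0])
        always = simulate_rescue(kip3_null, wt, 600, 1.0, 20, 4,
                                 all_immobile=True)
        still_lateral_at_switch = [tr for tr in always
                                   if tr.attachment[120] == "lateral"]
        assert all(tr.rescued for tr in still_lateral_at_switch)

    def test_rescued_count_matches_binomial_mean(self, wt, kip3_null):
        # 54 immobile kinetochores, p = 0.537 -> mean rescued ~ 29
        p_rescue, n, n_seeds = 0.537, 54, 40
        counts = [
            sum(tr.rescued for tr in simulate_rescue(
                kip3_null, wt, 600, p_rescue, n, seed, all_immobile=True))
            for seed in range(n_seeds)
        ]
        expected = n * p_rescue
        se = math.sqrt(n * p_rescue * (1 - p_rescue) / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_invalid_rescue_inputs(self, wt, kip3_null):
        with pytest.raises(ValueError):
            simulate_rescue(kip3_null, wt, 600, 1.5, 10, 0)
        with pytest.raises(ValueError):
            simulate_rescue(kip3_null, wt, 2000, 0.5, 10, 0, duration=1800)
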