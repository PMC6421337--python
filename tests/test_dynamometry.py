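"""Correction chain and extraction rules, each checked against the generator."""

import numpy as np
import pytest

from myopower.cohort import (
    TorqueTrace,
    fl_factor,
    sample_cohort,
    simulate_baseline_trial,
    simulate_cohort,
    simulate_isokinetic_trial,
    simulate_isometric_trial,
)
from myopower.dynamometry import (
    EmgMomentFit,
    compute_power,
    correct_antagonist,
    correct_axis_misalignment,
    correct_foot_gravity,
    correct_trace,
    extract_max_power,
    extract_mvc,
    fit_emg_moment,
    subtract_baseline,
)


def make_trace(moment, angle=None, angvel=None, ta_emg=None, d_dyn=10.0, d_ankle=10.0,
               mode="isokinetic", set_velocity=120.0):
    moment = np.asarray(moment, dtype=float)
    n = moment.size
    return TorqueTrace(
        mode=mode,
        set_velocity=set_velocity,
        time=np.arange(n) / 250.0,
        angle=np.zeros(n) if angle is None else np.asarray(angle, float),
        angvel=np.full(n, set_velocity) if angvel is None else np.asarray(angvel, float),
        moment=moment,
        ta_emg=np.zeros(n) if ta_emg is None else np.asarray(ta_emg, float),
        d_dyn=np.full(n, d_dyn),
        d_ankle=np.full(n, d_ankle),
    )


def single_layer_config(noise_free_config, **overrides):
    return noise_free_config.replace(**overrides)


class TestAxisMisalignment:
    def test_lever_ratio_proportionality(self):
        tr = make_trace([100.0], d_dyn=10.0, d_ankle=9.0)
        assert correct_axis_misalignment(tr)[0] == pytest.approx(90.0)

    def test_aligned_axes_identity(self):
        tr = make_trace([50.0, 80.0])
        np.testing.assert_array_equal(correct_axis_misalignment(tr), tr.moment)

    def test_nonpositive_lever_rejected(self):
        tr = make_trace([10.0], d_dyn=0.0)
        with pytest.raises(ValueError):
            correct_axis_misalignment(tr)

    def test_recovers_true_moment_from_offset_generator(self, noise_free_config):
        cfg = single_layer_config(noise_free_config, axis_ratio_low=0.9, axis_ratio_high=1.1)
        truth = sample_cohort(cfg)[0]
        tr = simulate_isometric_trial(truth, 0.0, cfg)
        corrected = correct_axis_misalignment(tr)
        expected = truth.f0_n * fl_factor(0.0) * truth.moment_arm / 100.0
        assert abs(corrected.max() - expected) < 0.1


class TestBaselineSubtraction:
    def test_zero_baseline_is_identity(self):
        tr = make_trace([100.0, 100.0], angle=[0.0, 1.0])
        base = make_trace([0.0, 0.0, 0.0], angle=[-20.0, 0.0, 20.0])
        np.testing.assert_allclose(subtract_baseline(tr, base), tr.moment)

    def test_constant_baseline(self):
        tr = make_trace([100.0], angle=[2.0])
        base = make_trace([5.0, 5.0], angle=[-20.0, 20.0])
        assert subtract_baseline(tr, base)[0] == pytest.approx(95.0)

    def test_velocity_mismatch_rejected(self):
        tr = make_trace([100.0], set_velocity=120.0)
        base = make_trace([5.0, 5.0], angle=[-20.0, 20.0], set_velocity=60.0)
        with pytest.raises(ValueError, match="set velocity"):
            subtract_baseline(tr, base)

    def test_uncovered_angle_range_rejected(self):
        tr = make_trace([100.0], angle=[19.0])
        base = make_trace([5.0, 5.0], angle=[-10.0, 10.0])
        with pytest.raises(ValueError, match="cover"):
            subtract_baseline(tr, base)

    def test_footplate_artefact_removed_below_rms_bound(self, noise_free_config, rng):
        cfg = single_layer_config(noise_free_config, footplate_amp_nm=4.0)
        truth = sample_cohort(cfg)[0]
        tr = simulate_isokinetic_trial(truth, 120.0, 0, cfg)
        base = simulate_baseline_trial(120.0, cfg, rng)
        corrected = subtract_baseline(tr, base, moment=correct_axis_misalignment(tr))
        from myopower.cohort import mixture_of
        from myopower.fibre_mechanics import mixture_force

        v_fib = truth.moment_arm / 100.0 * np.radians(tr.angvel)
        true_m = (
            truth.activation_isokinetic[2]
            * truth.f0_n
            * fl_factor(tr.angle)
            * mixture_force(v_fib, mixture_of(truth, cfg), truth.fibre_length / 100.0)
            * truth.moment_arm
            / 100.0
        )
        rms = np.sqrt(np.mean((corrected - true_m) ** 2))
        assert rms < 0.2


class TestFootGravity:
    def test_magnitude_of_correction(self):
        tr = make_trace([10.0], angle=[0.0])
        corrected = correct_foot_gravity(tr, foot_mass_kg=1.0, com_lever_m=0.10)
        assert (tr.moment - corrected)[0] == pytest.approx(0.981, abs=1e-3)

    def test_zero_lever_means_no_correction(self):
        tr = make_trace([10.0], angle=[0.0])
        np.testing.assert_allclose(correct_foot_gravity(tr, 1.0, 0.0), tr.moment)

    def test_recovers_true_moment_from_gravity_generator(self, noise_free_config):
        cfg = single_layer_config(noise_free_config, foot_gravity=True)
        truth = sample_cohort(cfg)[0]
        tr = simulate_isometric_trial(truth, 0.0, cfg)
        from myopower.cohort import FOOT_MASS_FRACTION

        corrected = correct_foot_gravity(tr, FOOT_MASS_FRACTION * truth.body_mass)
        expected = truth.f0_n * fl_factor(0.0) * truth.moment_arm / 100.0
        assert abs(corrected.max() - expected) < 0.1


class TestEmgMomentFit:
    def test_exact_line(self):
        fit = fit_emg_moment([0.2, 0.4], [10.0, 20.0])
        assert fit.gain == pytest.approx(50.0)
        assert fit.n_pairs == 2

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            fit_emg_moment([0.2], [10.0])

    def test_all_zero_emg_rejected(self):
        with pytest.raises(ValueError):
            fit_emg_moment([0.0, 0.0], [1.0, 2.0])


class TestAntagonistCorrection:
    def test_zero_emg_unchanged(self):
        fit = EmgMomentFit(50.0, 0.0, 2)
        np.testing.assert_allclose(
            correct_antagonist([100.0], [0.0], fit), [100.0]
        )

    def test_adds_back_dorsiflexion_moment(self):
        fit = EmgMomentFit(50.0, 0.0, 2)
        assert correct_antagonist([100.0], [0.05], fit)[0] == pytest.approx(102.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correct_antagonist([100.0, 90.0], [0.05], EmgMomentFit(50.0, 0.0, 2))

    def test_recovers_true_moment_from_coactivation_generator(self, noise_free_config):
        cfg = single_layer_config(noise_free_config, ta_coactivation=0.05)
        truth = sample_cohort(cfg)[0]
        tr = simulate_isometric_trial(truth, 0.0, cfg)
        fit = EmgMomentFit(truth.ta_gain, 0.0, 2)
        corrected = correct_antagonist(tr.moment, tr.ta_emg, fit)
        expected = truth.f0_n * fl_factor(0.0) * truth.moment_arm / 100.0
        assert abs(corrected.max() - expected) < 0.5


class TestExtraction:
    def test_mvc_max_rule(self):
        assert extract_mvc([[180.0, 150.0], [189.0], [185.0]]) == 189.0

    def test_mvc_single_trace(self):
        assert extract_mvc([[120.0, 140.0]]) == 140.0

    def test_mvc_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_mvc([])

    def test_power_unit_conversion(self):
        p = compute_power([100.0], [120.0])
        assert p[0] == pytest.approx(209.4395, abs=1e-3)
        assert compute_power([100.0], [0.0])[0] == 0.0
        assert compute_power([100.0], [-60.0])[0] < 0.0

    def test_window_average_and_max_of_three(self):
        def trial(power_w, v=120.0):
            moment = power_w / np.radians(v)
            return make_trace(np.full(20, moment), angle=np.linspace(-2, 7, 20), set_velocity=v)

        trials = {
            120.0: [(trial(120.0), trial(120.0).moment),
                    (trial(138.0), trial(138.0).moment),
                    (trial(130.0), trial(130.0).moment)]
        }
        res = extract_max_power(trials)
        assert res.per_velocity_power[120.0] == pytest.approx(138.0)
        assert res.max_power == pytest.approx(138.0)
        assert res.velocity_at_max == 120.0

    def test_tie_breaks_to_lowest_velocity(self):
        def trial(power_w, v):
            moment = power_w / np.radians(v)
            return make_trace(np.full(20, moment), angle=np.linspace(0, 5, 20), set_velocity=v)

        trials = {
            150.0: [(trial(150.0, 150.0), trial(150.0, 150.0).moment)],
            90.0: [(trial(150.0, 90.0), trial(150.0, 90.0).moment)],
        }
        assert extract_max_power(trials).velocity_at_max == 90.0

    def test_invariant_to_trial_order(self, small_cohort):
        subject = small_cohort.subjects[0]
        from myopower.dynamometry import analyze_subject_dynamometry

        fwd = analyze_subject_dynamometry(
            subject, small_cohort.baselines_isokinetic, small_cohort.baselines_isometric
        )
        shuffled = type(subject)(**{**subject.__dict__})
        shuffled.isokinetic = {v: list(reversed(t)) for v, t in subject.isokinetic.items()}
        rev = analyze_subject_dynamometry(
            shuffled, small_cohort.baselines_isokinetic, small_cohort.baselines_isometric
        )
        assert fwd["max_power_W"] == rev["max_power_W"]
        assert fwd["velocity_at_max_deg_s"] == rev["velocity_at_max_deg_s"]

    def test_empty_window_rejected(self):
        tr = make_trace(np.full(5, 10.0), angle=np.linspace(10, 15, 5))
        with pytest.raises(ValueError, match="window"):
            extract_max_power({120.0: [(tr, tr.moment)]})


class TestCorrectionChainProperties:
    def test_end_to_end_oracle_equivalence(self, clean_cohort, noise_free_config):
        """With every corruption layer off, the full chain reproduces the
        closed-form MVC and power model to better than 0.5%."""
        from myopower.cohort import expected_measures, window_fl_means
        from myopower.dynamometry import analyze_subject_dynamometry

        wfl = window_fl_means(noise_free_config)
        for subject in clean_cohort.subjects[:4]:
            out = analyze_subject_dynamometry(
                subject, clean_cohort.baselines_isokinetic, clean_cohort.baselines_isometric
            )
            exp = expected_measures(subject.truth, noise_free_config, wfl)
            assert out["mvc_moment_Nm"] == pytest.approx(exp["mvc_nm"], rel=5e-3)
            assert out["max_power_W"] == pytest.approx(exp["max_power_w"], rel=5e-3)
            assert out["velocity_at_max_deg_s"] == exp["velocity_at_max_deg_s"]

    def test_baseline_and_foot_gravity_commute(self, small_cohort):
        subject = small_cohort.subjects[0]
        trace = subject.isokinetic[120.0][0]
        base = small_cohort.baselines_isokinetic[120.0]
        foot_mass = subject.meta["foot_mass_kg"]
        m = correct_axis_misalignment(trace)
        order_a = correct_foot_gravity(
            trace, foot_mass, moment=subtract_baseline(trace, base, moment=m)
        )
        order_b = subtract_baseline(
            trace, base, moment=correct_foot_gravity(trace, foot_mass, moment=m)
        )
        assert np.max(np.abs(order_a - order_b)) < 0.1

    def test_correction_idempotence_with_null_second_pass(self):
        tr = make_trace(np.full(6, 100.0), angle=np.linspace(0, 5, 6))
        fit = EmgMomentFit(50.0, 0.0, 2)
        once = correct_antagonist(tr.moment, tr.ta_emg, fit)
        twice = correct_antagonist(once, np.zeros(6), fit)
        np.testing.assert_array_equal(once, twice)
        again = correct_foot_gravity(tr, 0.0, moment=once)
        np.testing.assert_array_equal(once, again)

    def test_window_mean_of_products_matches_product_of_means_on_plateau(
        self, clean_cohort
    ):
        # the two readings of "average power in the window" coincide on an
        # isokinetic plateau because angular velocity is constant there
        subject = clean_cohort.subjects[0]
        tr = subject.isokinetic[150.0][0]
        window = (tr.angle >= 0) & (tr.angle <= 5)
        m, w = tr.moment[window], np.radians(tr.angvel[window])
        assert np.mean(m * w) == pytest.approx(np.mean(m) * np.mean(w), rel=1e-3)
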