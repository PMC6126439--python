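import numpy as np
import pytest

from respimoco.acquisition import FrameSeries, acquire_dynamic_mr, acquire_pet
from respimoco.phantom import make_motion
from respimoco.surrogate import (DegenerateSignalError, align_clocks,
                                 extract_surrogate)
from respimoco.waveform import BreathingWaveform


def _sine_wave(duration, period=4.0):
    t = np.arange(0.0, duration + 1e-9, 0.05)
    return BreathingWaveform(t, 0.5 + 0.5 * np.sin(2 * np.pi * t / period),
                             np.array([]), np.array([]))


@pytest.fixture(scope="module")
def setup():
    from respimoco.phantom import build_phantom, default_spec
    ph = build_phantom(default_spec())
    # hysteresis off: the image state is then a pure function of s, which is
    # what a fidelity comparison against the amplitude alone requires
    mot = make_motion(ph, hysteresis_mm_s=0.0)
    return ph, mot


@pytest.fixture(scope="module")
def sine_frames(setup):
    ph, mot = setup
    return acquire_pet(ph.activity, ph.mu, mot, _sine_wave(60.0),
                       noise=False, duration=60.0)


class TestExtraction:
    def test_noiseless_surrogate_tracks_truth(self, sine_frames):
        surr = extract_surrogate(sine_frames)
        r = np.corrcoef(surr.s, sine_frames.hidden_s)[0, 1]
        assert abs(r) > 0.99

    def test_com_method_also_tracks_truth(self, sine_frames):
        surr = extract_surrogate(sine_frames, method="com")
        r = np.corrcoef(surr.s, sine_frames.hidden_s)[0, 1]
        assert abs(r) > 0.95

    def test_invariant_to_global_count_scaling(self, sine_frames):
        surr1 = extract_surrogate(sine_frames)
        scaled = FrameSeries(sinos=sine_frames.sinos * 7.5,
                             t_start=sine_frames.t_start,
                             durations=sine_frames.durations,
                             background=sine_frames.background,
                             calibration=sine_frames.calibration,
                             noisy=False, spacing_mm=sine_frames.spacing_mm,
                             n_angles=sine_frames.n_angles)
        surr2 = extract_surrogate(scaled)
        assert np.allclose(surr1.s, surr2.s, atol=1e-9)

    def test_sign_convention_deterministic(self, sine_frames):
        a = extract_surrogate(sine_frames)
        b = extract_surrogate(sine_frames)
        assert np.array_equal(a.s, b.s)
        # convention: s rises when counts move inferior => s follows truth
        r = np.corrcoef(a.s, sine_frames.hidden_s)[0, 1]
        assert r > 0

    def test_normalised_to_unit_interval(self, sine_frames):
        surr = extract_surrogate(sine_frames)
        assert surr.s.min() == pytest.approx(0.0, abs=1e-12)
        assert surr.s.max() == pytest.approx(1.0, abs=1e-12)

    def test_sdot_amplitude_of_pure_sine(self, setup):
        # for s = sin(w t): max|sdot| / max|s - mean| = w, up to the
        # central-difference sinc factor (kept < 3% by 0.25-s frames)
        ph, mot = setup
        frames = acquire_pet(ph.activity, ph.mu, mot, _sine_wave(40.0),
                             noise=False, duration=40.0, frame_duration=0.25)
        surr = extract_surrogate(frames)
        omega = 2 * np.pi / 4.0
        ratio = np.abs(surr.sdot).max() / np.abs(surr.s - surr.s.mean()).max()
        assert ratio == pytest.approx(omega, rel=0.05)

    def test_motionless_acquisition_flags_degenerate(self, setup):
        ph, mot = setup
        t = np.arange(0.0, 10.0 + 1e-9, 0.05)
        still = BreathingWaveform(t, np.zeros_like(t), np.array([]),
                                  np.array([]))
        frames = acquire_pet(ph.activity, ph.mu, mot, still, noise=False,
                             duration=10.0)
        surr = extract_surrogate(frames)
        assert surr.degenerate
        assert np.all(surr.s == 0.0)

    def test_all_zero_frames_rejected(self, sine_frames):
        zero = FrameSeries(sinos=np.zeros_like(sine_frames.sinos),
                           t_start=sine_frames.t_start,
                           durations=sine_frames.durations,
                           background=sine_frames.background,
                           calibration=1.0, noisy=False,
                           spacing_mm=3.0, n_angles=sine_frames.n_angles)
        with pytest.raises(DegenerateSignalError):
            extract_surrogate(zero)

    def test_projection_of_new_frames_matches_training_values(
            self, sine_frames):
        surr = extract_surrogate(sine_frames)
        s_again = surr.s_of_frames(sine_frames)
        # projecting the training frames reproduces the unsmoothed score;
        # agreement up to the smoothing residual
        assert np.corrcoef(s_again, surr.s)[0, 1] > 0.995


class TestClockAlignment:
    @pytest.fixture(scope="class")
    def pet_side(self, setup):
        # variable breathing (cycle-to-cycle amplitude/period draws): a pure
        # sinusoid would leave the time shift ambiguous modulo one period
        from respimoco.waveform import make_waveform
        ph, mot = setup
        wave = make_waveform(120.0, seed=21)
        frames = acquire_pet(ph.activity, ph.mu, mot, wave, noise=False,
                             duration=120.0)
        return ph, mot, wave, extract_surrogate(frames)

    @pytest.mark.parametrize("tau", [-2.0, 0.0, 3.5])
    def test_injected_shift_recovered(self, pet_side, tau):
        ph, mot, wave, surr = pet_side
        mr = acquire_dynamic_mr(ph, mot, wave, duration=40.0,
                                start_time=60.0, clock_offset=tau,
                                noise_sigma=0.01, seed=3)
        align = align_clocks(surr, mr)
        assert abs(align.tau - tau) <= 0.25

    def test_objective_at_optimum_dominates_grid(self, pet_side):
        ph, mot, wave, surr = pet_side
        mr = acquire_dynamic_mr(ph, mot, wave, duration=40.0,
                                start_time=60.0, clock_offset=1.0,
                                noise_sigma=0.01, seed=3)
        align = align_clocks(surr, mr)
        assert align.objective >= np.nanmax(
            align.objective_grid[np.isfinite(align.objective_grid)]) - 1e-12

    def test_flat_trace_rejected(self, pet_side):
        ph, mot, wave, surr = pet_side
        mr = acquire_dynamic_mr(ph, mot, wave, duration=40.0,
                                start_time=60.0, noise_sigma=0.01, seed=3)
        with pytest.raises(DegenerateSignalError):
            align_clocks(surr, mr, trace=np.zeros(mr.n_images))

    def test_non_overlapping_windows_rejected(self, pet_side):
        ph, mot, wave, surr = pet_side
        mr = acquire_dynamic_mr(ph, mot, wave, duration=40.0,
                                start_time=60.0, noise_sigma=0.01, seed=3)
        mr.t_mr = mr.t_mr + 1e4  # far outside the PET window
        with pytest.raises(ValueError, match="overlap"):
            align_clocks(surr, mr, tau_bound=2.0)

    def test_rate_coestimation_keeps_endpoint_error_small(self, pet_side):
        ph, mot, wave, surr = pet_side
        rate = 1.0 + 1e-4
        mr = acquire_dynamic_mr(ph, mot, wave, duration=40.0,
                                start_time=60.0, clock_rate=rate,
                                clock_offset=0.5, noise_sigma=0.01, seed=3)
        align = align_clocks(surr, mr, estimate_rate=True)
        t_end_true = (mr.t_mr[-1] - 0.5) / rate
        t_end_est = align.to_pet_time(mr.t_mr[-1])
        assert abs(t_end_est - t_end_true) < 0.25
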