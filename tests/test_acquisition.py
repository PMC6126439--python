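import numpy as np
import pytest

from respimoco.acquisition import (acquire_breathhold_frames,
                                   acquire_dynamic_mr, acquire_mumap,
                                   acquire_pet, poisson_sample_frames)
from respimoco.phantom import make_motion
from respimoco.waveform import BreathingWaveform, make_waveform


def _sine_wave(duration=30.0, period=4.0, amp=1.0):
    t = np.arange(0.0, duration + 1e-9, 0.05)
    return BreathingWaveform(t, amp * (0.5 + 0.5 * np.sin(2 * np.pi * t / period)),
                             np.array([]), np.array([]))


def _still_wave(duration=20.0):
    t = np.arange(0.0, duration + 1e-9, 0.05)
    return BreathingWaveform(t, np.zeros_like(t), np.array([]), np.array([]))


@pytest.fixture(scope="module")
def still_frames(small_phantom_mod, small_motion_mod):
    ph, mot = small_phantom_mod, small_motion_mod
    return acquire_pet(ph.activity, ph.mu, mot, _still_wave(), noise=False,
                       duration=20.0, n_angles=42)


@pytest.fixture(scope="module")
def small_phantom_mod():
    from respimoco.phantom import PhantomSpec, Lesion, build_phantom
    spec = PhantomSpec(grid_shape=(64, 64), spacing_mm=(3.0, 3.0),
                       lesions=[Lesion((105.0, 126.0), 12.0, 12.0)])
    return build_phantom(spec)


@pytest.fixture(scope="module")
def small_motion_mod(small_phantom_mod):
    return make_motion(small_phantom_mod)


class TestPET:
    def test_240s_window_at_half_second_frames_gives_480_frames(
            self, small_phantom_mod, small_motion_mod):
        ph, mot = small_phantom_mod, small_motion_mod
        wave = make_waveform(240.0, seed=0)
        fr = acquire_pet(ph.activity, ph.mu, mot, wave, frame_duration=0.5,
                         noise=False, n_angles=14)
        assert fr.n_frames == 480

    def test_motionless_noiseless_frames_identical(self, still_frames):
        assert np.allclose(still_frames.sinos, still_frames.sinos[0])

    def test_poisson_total_within_3_sigma(self, small_phantom_mod,
                                          small_motion_mod):
        ph, mot = small_phantom_mod, small_motion_mod
        wave = _sine_wave()
        fr0 = acquire_pet(ph.activity, ph.mu, mot, wave, noise=False,
                          duration=30.0, n_angles=42)
        fr = acquire_pet(ph.activity, ph.mu, mot, wave, noise=True, seed=7,
                         duration=30.0, n_angles=42)
        expected = fr0.total_counts
        assert abs(fr.total_counts - expected) <= 3 * np.sqrt(expected)
        # Poisson counts are integers, so frame sums add exactly
        assert fr.total_counts == sum(float(s.sum()) for s in fr.sinos)

    def test_target_total_counts_calibration(self, still_frames):
        assert still_frames.total_counts == pytest.approx(
            3e6 * 1.1, rel=1e-6)  # trues + 10% uniform background

    def test_bad_frame_duration_rejected(self, small_phantom_mod,
                                         small_motion_mod):
        ph, mot = small_phantom_mod, small_motion_mod
        with pytest.raises(ValueError):
            acquire_pet(ph.activity, ph.mu, mot, _still_wave(),
                        frame_duration=-1.0)
        with pytest.raises(ValueError):
            acquire_pet(ph.activity, ph.mu, mot, _still_wave(),
                        frame_duration=0.7, duration=20.0)

    def test_poisson_resampling_requires_expected_counts(self, still_frames):
        noisy = poisson_sample_frames(still_frames, seed=1)
        assert noisy.noisy
        with pytest.raises(ValueError):
            poisson_sample_frames(noisy, seed=2)


class TestDynamicMR:
    def test_one_minute_gives_200_images_cycling_9_positions(
            self, small_phantom_mod, small_motion_mod):
        wave = make_waveform(240.0, seed=0)
        mr = acquire_dynamic_mr(small_phantom_mod, small_motion_mod, wave,
                                duration=60.0, start_time=180.0, seed=1)
        assert mr.n_images == 200
        counts = np.bincount(mr.slice_position)[1:]
        assert counts.min() >= 22 and counts.max() <= 23

    def test_motionless_images_at_one_position_identical(
            self, small_phantom_mod, small_motion_mod):
        mr = acquire_dynamic_mr(small_phantom_mod, small_motion_mod,
                                _still_wave(30.0), duration=27.0,
                                start_time=0.0, noise_sigma=0.0, seed=1)
        sel = mr.images[mr.slice_position == 3]
        assert np.allclose(sel, sel[0])

    def test_diaphragm_edge_oscillates_with_waveform_period(
            self, small_phantom_mod, small_motion_mod):
        """Edge-tracking oracle on noiseless images: the dominant frequency
        of the diaphragm-edge trace equals the breathing frequency."""
        from respimoco.surrogate import mr_diaphragm_trace
        period = 4.0
        mr = acquire_dynamic_mr(small_phantom_mod, small_motion_mod,
                                _sine_wave(48.0, period), duration=48.0,
                                start_time=0.0, noise_sigma=0.0, seed=1)
        trace = mr_diaphragm_trace(mr)
        trace = trace - trace.mean()
        dt = mr.image_duration
        freqs = np.fft.rfftfreq(len(trace), dt)
        spectrum = np.abs(np.fft.rfft(trace))
        f_peak = freqs[1:][np.argmax(spectrum[1:])]
        assert f_peak == pytest.approx(1.0 / period, abs=0.05)

    def test_mr_clock_mapping(self, small_phantom_mod, small_motion_mod):
        mr = acquire_dynamic_mr(small_phantom_mod, small_motion_mod,
                                _still_wave(30.0), duration=27.0,
                                start_time=0.0, clock_rate=1.0 + 1e-4,
                                clock_offset=2.0, seed=1)
        assert np.allclose(mr.t_mr, (1 + 1e-4) * mr.hidden_t_pet + 2.0)

    def test_invalid_rate_rejected(self, small_phantom_mod,
                                   small_motion_mod):
        with pytest.raises(ValueError):
            acquire_dynamic_mr(small_phantom_mod, small_motion_mod,
                               _still_wave(), clock_rate=0.0)


class TestMuMap:
    def test_reference_state_returns_mu_exactly(self, small_phantom_mod,
                                                small_motion_mod):
        acq = acquire_mumap(small_phantom_mod.mu, small_motion_mod,
                            (0.0, 0.0))
        assert np.array_equal(acq.mu.values, small_phantom_mod.mu.values)

    def test_inhale_state_shifts_diaphragm_by_excursion(
            self, small_phantom_mod, small_motion_mod):
        """Boundary oracle: locate the lung/liver mu edge in a column band
        before and after warping to full inhale."""
        ph, mot = small_phantom_mod, small_motion_mod
        acq = acquire_mumap(ph.mu, mot, (1.0, 0.0))
        col = int(0.66 * ph.mu.shape[1])
        dz = ph.mu.spacing[0]
        z_dia = int(round(ph.diaphragm_z_mm / dz))

        def edge_row(mu):
            # strongest lung->liver rise near the diaphragm
            prof = mu[:, col]
            grad = np.gradient(prof)
            lo, hi = z_dia - 6, z_dia + 10
            return lo + int(np.argmax(grad[lo:hi]))

        shift_mm = (edge_row(acq.mu.values) - edge_row(ph.mu.values)) * dz
        expected = 20.0 * mot.amplitude_at((edge_row(ph.mu.values) * dz, 0))
        assert shift_mm == pytest.approx(expected, abs=1.5 * dz)

    def test_state_beyond_waveform_range_permitted(self, small_phantom_mod,
                                                   small_motion_mod):
        acq = acquire_mumap(small_phantom_mod.mu, small_motion_mod,
                            (1.4, 0.0))
        assert acq.state == (1.4, 0.0)

    def test_breathhold_segment_records_constant_state(
            self, small_phantom_mod, small_motion_mod):
        ph, mot = small_phantom_mod, small_motion_mod
        fr = acquire_breathhold_frames(ph.activity, ph.mu, mot, (1.2, 0.0),
                                       duration=3.0, calibration=1e-5,
                                       noise=False, n_angles=42)
        assert fr.n_frames == 6
        assert np.allclose(fr.hidden_s, 1.2)
        assert np.allclose(fr.sinos, fr.sinos[0])
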