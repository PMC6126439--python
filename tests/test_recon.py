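import numpy as np
import pytest

from respimoco.acquisition import acquire_mumap, acquire_pet
from respimoco.motionmodel import MotionModelResult
from respimoco.phantom import make_motion
from respimoco.projector import get_projector
from respimoco.recon import (EmptyGateError, GatingScheme, ReconSettings,
                             make_gates, osem, recon_motion_corrected,
                             recon_uncorrected)
from respimoco.surrogate import extract_surrogate
from respimoco.waveform import BreathingWaveform, make_waveform


def _wave(duration, amp=1.0):
    t = np.arange(0.0, duration + 1e-9, 0.05)
    s = amp * (0.5 + 0.5 * np.sin(2 * np.pi * t / 4.0))
    return BreathingWaveform(t, s, np.array([]), np.array([]))


@pytest.fixture(scope="module")
def setup(small_phantom, small_motion):
    proj = get_projector(small_phantom.activity.shape,
                         small_phantom.activity.spacing, 42)
    frames = acquire_pet(small_phantom.activity, small_phantom.mu,
                         small_motion, make_waveform(120.0, seed=4),
                         noise=True, seed=5, n_angles=42,
                         target_total_counts=1.5e6)
    mumap = acquire_mumap(small_phantom.mu, small_motion, (0.0, 0.0))
    return small_phantom, small_motion, proj, frames, mumap


class TestGating:
    def test_equal_count_amplitude_gates(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        gates = make_gates(surr, frames, 8)
        assert gates.gate_sizes.sum() == frames.n_frames
        assert gates.gate_sizes.min() >= frames.n_frames // 8
        assert gates.gate_sizes.max() <= frames.n_frames // 8 + 1

    def test_counts_partition_exactly(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        gates = make_gates(surr, frames, 8)
        total = sum(frames.pooled(gates.frames_in(g))[0].sum()
                    for g in range(8))
        assert total == frames.total_counts  # integer identity

    def test_amplitude_direction_scheme_splits_by_sign(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        gates = make_gates(surr, frames, 8, scheme="amplitude-direction")
        for g in range(4):
            assert np.all(surr.sdot[gates.frames_in(g)] >= 0)
        for g in range(4, 8):
            assert np.all(surr.sdot[gates.frames_in(g)] < 0)

    def test_too_many_gates_rejected(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        with pytest.raises(ValueError):
            make_gates(surr, frames, frames.n_frames + 1)

    def test_empty_gate_refused(self):
        with pytest.raises(EmptyGateError):
            GatingScheme(frame_gate=np.array([0, 0, 2, 2]), n_gates=3,
                         rep_states=np.zeros((3, 2)), scheme="amplitude",
                         frame_counts=np.ones(4))


class TestOsem:
    def test_all_zero_data_gives_zero_image(self, setup):
        ph, mot, proj, frames, mumap = setup
        atten = proj.attenuation_factors(mumap.mu.values)
        img = osem(np.zeros((42, proj.n_rad)), atten,
                   ReconSettings(21, 1, 0.0), proj, scale=1.0)
        assert np.all(img.values == 0.0)

    def test_nonnegativity_preserved(self, setup):
        ph, mot, proj, frames, mumap = setup
        img = recon_uncorrected(frames, mumap, ReconSettings(21, 3, 4.0),
                                proj)
        assert np.all(img.values >= 0.0)

    def test_postfilter_preserves_interior_activity(self, setup):
        ph, mot, proj, frames, mumap = setup
        img = recon_uncorrected(frames, mumap, ReconSettings(21, 3, 4.0),
                                proj)
        total_raw = img.unfiltered.sum()
        total_filtered = img.values.sum()
        assert abs(total_filtered - total_raw) / total_raw < 0.005

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            ReconSettings(subsets=0)
        with pytest.raises(ValueError):
            ReconSettings(iterations=0)
        with pytest.raises(ValueError):
            ReconSettings(postfilter_fwhm_mm=-1.0)
        with pytest.raises(ValueError):
            ReconSettings(mode="bogus")

    def test_non_divisor_subsets_warns_and_runs(self, setup):
        ph, mot, proj, frames, mumap = setup
        with pytest.warns(UserWarning, match="near-equal"):
            recon_uncorrected(frames, mumap, ReconSettings(20, 1, 0.0), proj)


class TestMotionCorrected:
    def test_zero_model_equals_uncorrected(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        settings = ReconSettings(21, 3, 4.0)
        u = recon_uncorrected(frames, mumap, settings, proj)
        model = MotionModelResult.zero(ph.activity.shape,
                                       ph.activity.spacing)
        for n_gates in (1, 8):
            gates = make_gates(surr, frames, n_gates)
            mc = recon_motion_corrected(
                frames, mumap, model, gates,
                ReconSettings(21, 3, 4.0, mode="motion-corrected"), proj,
                mu_state=(0.0, 0.0))
            rel = np.abs(mc.values - u.values).max() / u.values.max()
            assert rel < 1e-9

    def test_mc_recon_uses_all_counts(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        gates = make_gates(surr, frames, 8)
        model = MotionModelResult.zero(ph.activity.shape,
                                       ph.activity.spacing)
        mc = recon_motion_corrected(frames, mumap, model, gates,
                                    ReconSettings(21, 1, 0.0,
                                                  mode="motion-corrected"),
                                    proj, mu_state=(0.0, 0.0))
        assert mc.provenance["counts_used"] == frames.total_counts

    def test_missing_mu_state_is_configuration_error(self, setup):
        ph, mot, proj, frames, mumap = setup
        surr = extract_surrogate(frames)
        gates = make_gates(surr, frames, 4)
        model = MotionModelResult.zero(ph.activity.shape,
                                       ph.activity.spacing)
        with pytest.raises(ValueError, match="mu-map"):
            recon_motion_corrected(frames, mumap, model, gates,
                                   ReconSettings(21, 1, 0.0,
                                                 mode="motion-corrected"),
                                   proj)

    def test_rta_mode_approximates_mcir(self, setup):
        """The two motion-compensation algorithms agree on the large scale
        (identical data and model; different algorithms)."""
        ph, mot, proj, frames, mumap = setup
        from respimoco.experiments import truth_model, truth_surrogate
        surr = truth_surrogate(frames)
        model = truth_model(mot)
        gates = make_gates(surr, frames, 4)
        mcir = recon_motion_corrected(
            frames, mumap, model, gates,
            ReconSettings(21, 3, 4.0, mode="motion-corrected"),
            proj, mu_state=(0.0, 0.0))
        rta = recon_motion_corrected(
            frames, mumap, model, gates,
            ReconSettings(21, 3, 4.0, mode="motion-corrected",
                          mc_algorithm="rta"),
            proj, mu_state=(0.0, 0.0))
        inside = ph.body_mask
        num = np.abs(mcir.values - rta.values)[inside].mean()
        den = mcir.values[inside].mean()
        assert num / den < 0.25


def test_motion_blurs_lesion_fwhm(small_phantom, small_motion):
    """Uncorrected reconstruction of a moving lesion is wider along the
    motion axis than the motion-free reconstruction."""
    ph, mot = small_phantom, small_motion
    proj = get_projector(ph.activity.shape, ph.activity.spacing, 42)
    mot0 = make_motion(ph, excursion_mm=0.0, hysteresis_mm_s=0.0)
    settings = ReconSettings(21, 3, 4.0)

    def axial_width(img):
        mask = ph.lesion_masks[0]
        zc, xc = np.argwhere(mask).mean(axis=0).astype(int)
        prof = img.values[:, xc]
        prof = prof - np.median(prof)
        half = prof.max() / 2.0
        return np.sum(prof > half)

    widths = {}
    for name, m in (("moving", mot), ("still", mot0)):
        frames = acquire_pet(ph.activity, ph.mu, m, _wave(60.0),
                             noise=False, duration=60.0, n_angles=42)
        mumap = acquire_mumap(ph.mu, m, (0.0, 0.0))
        widths[name] = axial_width(
            recon_uncorrected(frames, mumap, settings, proj))
    assert widths["moving"] > widths["still"]
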