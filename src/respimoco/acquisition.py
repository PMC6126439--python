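"""Simulated PET / dynamic-MR / attenuation-map acquisition.

The PET acquisition is a stand-in for list mode: the 4-minute scan window is
cut into short contiguous frames (0.5 s default, resolving a 4-s breathing
cycle), and each frame's expected sinogram is the attenuated parallel-beam
projection of the phantom warped to the frame's instantaneous respiratory
state.  Poisson noise is optional; count conservation is exact.  The true
surrogate state at each frame midpoint is recorded as *hidden* truth for
validation only — the correction pipeline never reads it.

Scatter and randoms are emulated as a known uniform additive sinogram
background (default 10% of trues) that is handed to the reconstruction as its
additive term; physical estimation of scatter/randoms is out of scope.

The dynamic MR acquisition emulates a 1-minute free-breathing multislice
sequence: 0.3 s per image, cycling 9 slice positions, timestamps on an MR
clock that may tick at a slightly different rate than the PET clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DisplacementField, VoxelVolume, warp_array
from .phantom import GroundTruthMotion, Phantom
from .projector import Projector, get_projector
from .waveform import BreathingWaveform

__all__ = ["FrameSeries", "DynamicMRSeries", "MuMapAcquisition",
           "acquire_pet", "acquire_dynamic_mr", "acquire_mumap",
           "acquire_breathhold_frames"]


@dataclass
class FrameSeries:
    """Time-binned sinogram frames (expected or Poisson counts)."""

    sinos: np.ndarray          # (n_frames, n_angles, n_rad)
    t_start: np.ndarray        # frame start times, s (PET clock)
    durations: np.ndarray      # frame durations, s
    background: np.ndarray     # known additive expected counts per bin, per frame
    calibration: float         # counts per (kBq/mL * mm * s) along a line
    noisy: bool
    spacing_mm: float
    n_angles: int
    hidden_s: np.ndarray = None      # validation-only truth
    hidden_sdot: np.ndarray = None

    def __post_init__(self):
        self.sinos = np.asarray(self.sinos, dtype=float)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if np.any(self.sinos < 0):
            raise ValueError("counts must be >= 0")
        ends = self.t_start + self.durations
        if not np.allclose(ends[:-1], self.t_start[1:]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.sinos.shape[0]

    @property
    def t_mid(self) -> np.ndarray:
        return self.t_start + 0.5 * self.durations

    @property
    def frame_counts(self) -> np.ndarray:
        return self.sinos.sum(axis=(1, 2))

    @property
    def total_counts(self) -> float:
        return float(self.sinos.sum())

    def pooled(self, frame_idx=None):
        """Sum of frame sinograms and of their additive backgrounds."""
        idx = np.arange(self.n_frames) if frame_idx is None else np.asarray(frame_idx)
        sino = self.sinos[idx].sum(axis=0)
        bkg = float(self.background[idx].sum())
        dur = float(self.durations[idx].sum())
        return sino, bkg, dur


@dataclass
class DynamicMRSeries:
    """Ordered 2D MR snapshots cycling the slice positions."""

    images: np.ndarray         # (n_images, nz, nx)
    slice_position: np.ndarray  # 1-based position index, cycling 1..n_pos
    t_mr: np.ndarray           # acquisition timestamps on the MR clock, s
    n_positions: int
    image_duration: float      # s per image
    spacing_mm: tuple
    clock_rate: float = 1.0    # true MR/PET clock-rate factor (hidden)
    clock_offset: float = 0.0  # true MR-clock offset tau, s (hidden)
    hidden_t_pet: np.ndarray = None
    hidden_s: np.ndarray = None
    hidden_sdot: np.ndarray = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.t_mr = np.asarray(self.t_mr, dtype=float)
        if np.any(np.diff(self.t_mr) <= 0):
            raise ValueError("MR timestamps must be strictly increasing")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


@dataclass
class MuMapAcquisition:
    """A breath-hold attenuation map and the respiratory state it was
    acquired at.  ``surrogate_frames`` is a short PET segment recorded during
    the breath-hold, from which the pipeline later measures the map's
    surrogate value in model units (the acquisition state itself is hidden
    truth)."""

    mu: VoxelVolume
    state: tuple               # (s, sdot), hidden truth
    surrogate_frames: FrameSeries = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.state)):
            raise ValueError("acquisition state must be finite")
        if np.any(self.mu.values < 0):
            raise ValueError("mu must be >= 0")


def _expected_frame_sino(proj: Projector, act: np.ndarray, mu: np.ndarray,
                         fld: DisplacementField) -> np.ndarray:
    """Attenuated line integrals of the warped phantom (per unit time/cal)."""
    act_w = warp_array(act, fld)
    mu_w = warp_array(mu, fld)
    sino = proj.forward_unblurred(act_w) * np.exp(
        -0.1 * proj.forward_unblurred(mu_w))
    return proj._psf(sino)


def acquire_pet(activity: VoxelVolume, mu: VoxelVolume,
                motion: GroundTruthMotion, wave: BreathingWaveform,
                frame_duration: float = 0.5, duration: float = None,
                noise: bool = True, seed=0, n_angles: int = 126,
                target_total_counts: float = 3e6, calibration: float = None,
                background_fraction: float = 0.1,
                psf_fwhm_mm: float = 0.0) -> FrameSeries:
    """Simulate a time-binned PET acquisition of the breathing phantom.

    Each frame: the phantom (activity and mu) is warped to the waveform state
    at the frame midpoint, projected, attenuated, scaled by duration and
    calibration, given the uniform additive background, and Poisson-sampled
    when ``noise``.  ``target_total_counts`` fixes the calibration so the
    noise-free trues over the whole window hit the requested count level
    (unless an explicit ``calibration`` is given).
    """
    if frame_duration <= 0:
        raise ValueError("frame duration must be > 0")
    if duration is None:
        duration = wave.duration
    n_frames = int(round(duration / frame_duration))
    if abs(n_frames * frame_duration - duration) > 1e-9:
        raise ValueError("frame duration must divide the scan window")

    proj = get_projector(activity.shape, activity.spacing, n_angles,
                         psf_fwhm_mm)
    t_start = np.arange(n_frames) * frame_duration
    t_mid = t_start + 0.5 * frame_duration
    s = wave.s_at(t_mid)
    sdot = wave.sdot_at(t_mid)

    expected = np.empty((n_frames, proj.n_angles, proj.n_rad))
    for i in range(n_frames):
        fld = motion.motion_at(s[i], sdot[i])
        expected[i] = _expected_frame_sino(proj, activity.values, mu.values,
                                           fld)
    expected *= frame_duration
    if calibration is None:
        total = expected.sum()
        calibration = (target_total_counts / total) if total > 0 else 1.0
    expected *= calibration

    # uniform additive background (scatter/randoms stand-in): constant rate,
    # so each frame's share is proportional to its live time
    n_bins = proj.n_angles * proj.n_rad
    total_trues = expected.sum()
    bkg = (background_fraction * total_trues / n_bins
           * np.asarray([frame_duration] * n_frames) / duration)
    expected += bkg[:, None, None]

    if noise:
        rng = np.random.default_rng(seed)
        sinos = rng.poisson(expected).astype(float)
    else:
        sinos = expected

    return FrameSeries(sinos=sinos, t_start=t_start,
                       durations=np.full(n_frames, float(frame_duration)),
                       background=bkg, calibration=float(calibration),
                       noisy=bool(noise), spacing_mm=proj.spacing,
                       n_angles=proj.n_angles, hidden_s=s, hidden_sdot=sdot)


def poisson_sample_frames(frames: FrameSeries, seed) -> FrameSeries:
    """Poisson realisation of a noise-free FrameSeries (expected counts).

    Lets one expensive expectation computation serve many noise seeds."""
    if frames.noisy:
        raise ValueError("frames are already a Poisson sample")
    rng = np.random.default_rng(seed)
    return FrameSeries(sinos=rng.poisson(frames.sinos).astype(float),
                       t_start=frames.t_start.copy(),
                       durations=frames.durations.copy(),
                       background=frames.background.copy(),
                       calibration=frames.calibration, noisy=True,
                       spacing_mm=frames.spacing_mm,
                       n_angles=frames.n_angles,
                       hidden_s=frames.hidden_s,
                       hidden_sdot=frames.hidden_sdot)


def acquire_dynamic_mr(phantom: Phantom, motion: GroundTruthMotion,
                       wave: BreathingWaveform, duration: float = 60.0,
                       start_time: float = 180.0, image_duration: float = 0.3,
                       n_positions: int = 9, clock_rate: float = 1.0,
                       clock_offset: float = 0.0, noise_sigma: float = 0.02,
                       seed=0) -> DynamicMRSeries:
    """Simulate the 1-min free-breathing dynamic MR acquisition.

    Images are snapshots of the MR contrast map warped to the instantaneous
    state, cycling ``n_positions`` slice positions at ``image_duration``
    seconds per image.  In the default 2D coronal geometry the position index
    is an acquisition-interleave label (all positions view the same plane);
    in 3D it selects sagittal planes.  Timestamps are written on the MR
    clock: ``t_mr = clock_rate * t_pet + clock_offset``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if clock_rate <= 0:
        raise ValueError("clock rate factor must be > 0")
    n_images = int(round(duration / image_duration))
    rng = np.random.default_rng(seed)

    t_pet = start_time + (np.arange(n_images) + 0.5) * image_duration
    s = wave.s_at(t_pet)
    sdot = wave.sdot_at(t_pet)
    positions = (np.arange(n_images) % n_positions) + 1

    contrast = phantom.mr_contrast.values
    images = np.empty((n_images,) + contrast.shape)
    for i in range(n_images):
        fld = motion.motion_at(s[i], sdot[i])
        img = warp_array(contrast, fld)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        images[i] = img

    t_mr = clock_rate * t_pet + clock_offset
    return DynamicMRSeries(images=images, slice_position=positions,
                           t_mr=t_mr, n_positions=n_positions,
                           image_duration=float(image_duration),
                           spacing_mm=phantom.mr_contrast.spacing,
                           clock_rate=float(clock_rate),
                           clock_offset=float(clock_offset),
                           hidden_t_pet=t_pet, hidden_s=s, hidden_sdot=sdot)


def acquire_mumap(mu: VoxelVolume, motion: GroundTruthMotion,
                  state=(0.0, 0.0)) -> MuMapAcquisition:
    """Acquire the static attenuation map at an arbitrary breath-hold state.

    The state may lie outside the free-breathing range (e.g. a deep exhale or
    inhale), which forces the motion model to extrapolate when the map is
    later brought back to the reference state.
    """
    s, sdot = float(state[0]), float(state[1])
    fld = motion.motion_at(s, sdot)
    mu_w = mu.with_values(warp_array(mu.values, fld))
    return MuMapAcquisition(mu=mu_w, state=(s, sdot))


def acquire_breathhold_frames(activity: VoxelVolume, mu: VoxelVolume,
                              motion: GroundTruthMotion, state,
                              duration: float = 5.0,
                              frame_duration: float = 0.5,
                              calibration: float = 1e-5, noise: bool = True,
                              seed=0, n_angles: int = 126,
                              background_fraction: float = 0.1) -> FrameSeries:
    """Short PET segment at a held respiratory state.

    Emulates the list-mode data available while the breath-hold attenuation
    map is acquired; the surrogate extracted from these frames gives the
    map's respiratory signal value the way the clinical method measures it.
    """
    t = np.arange(0.0, duration + 1e-9, 0.05)
    const = BreathingWaveform(t, np.full_like(t, float(state[0])),
                              np.array([]), np.array([]))
    # constant waveform => sdot 0; the held s is what matters
    return acquire_pet(activity, mu, motion, const,
                       frame_duration=frame_duration, duration=duration,
                       noise=noise, seed=seed, n_angles=n_angles,
                       calibration=calibration,
                       background_fraction=background_fraction)
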