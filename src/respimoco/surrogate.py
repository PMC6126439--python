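"""PET-derived respiratory surrogate and PET/MR clock alignment.

The surrogate is extracted from the time-binned PET data alone — no belt, no
navigator.  Default construction: the first principal-component score of the
mean-centred frame sinograms, a standard data-driven respiratory signal; a
centre-of-mass alternative is provided.  The sign is fixed so the surrogate
correlates positively with the axial (superior->inferior) centre of mass of
counts, the normalisation to [0, 1] is frozen over the acquisition window,
and the gradient is taken on a Savitzky-Golay-smoothed copy.

MR timestamps live on a different hardware clock; `align_clocks` recovers the
time shift (and optionally the clock-rate factor) by maximising the
correlation between the PET surrogate and a diaphragm-edge trace extracted
from the dynamic MR images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .acquisition import DynamicMRSeries, FrameSeries

__all__ = ["SurrogateSeries", "ClockAlignment", "extract_surrogate",
           "align_clocks", "mr_diaphragm_trace"]


class DegenerateSignalError(ValueError):
    """Raised when the frame data carry no usable respiratory signal."""


def _rebin(sinos: np.ndarray, factor: int) -> np.ndarray:
    """Coarse (angle x radial) rebinning: boosts per-bin statistics before
    the principal-component analysis without touching the timing."""
    if factor <= 1:
        return sinos
    nf, na, nr = sinos.shape
    na2, nr2 = na // factor * factor, nr // factor * factor
    return (sinos[:, :na2, :nr2]
            .reshape(nf, na2 // factor, factor, nr2 // factor, factor)
            .sum(axis=(2, 4)))


@dataclass
class SurrogateTransform:
    """Frozen map from a raw frame sinogram to the normalised surrogate."""
    mean: np.ndarray       # feature-space mean of the (rebinned) frames
    component: np.ndarray  # first principal axis (feature space), sign-fixed
    s_min: float
    s_max: float
    method: str
    rebin: int = 1

    def score(self, sinos: np.ndarray) -> np.ndarray:
        if self.method == "com":
            return _axial_com(sinos)
        X = _rebin(sinos, self.rebin).reshape(sinos.shape[0], -1)
        return (X - self.mean) @ self.component

    def normalise(self, raw: np.ndarray) -> np.ndarray:
        span = self.s_max - self.s_min
        if span <= 0:
            return np.zeros_like(raw)
        return (raw - self.s_min) / span


@dataclass
class SurrogateSeries:
    """Normalised surrogate s(t) and gradient on the PET clock."""

    t: np.ndarray          # frame midpoints, s
    s: np.ndarray          # normalised to [0, 1] over the window
    sdot: np.ndarray       # a.u./s, derivative of the smoothed s
    transform: SurrogateTransform
    smoothing_s: float
    degenerate: bool = False
    noise_sd: float = 0.0      # estimated per-frame score noise (s units)
    reliability: float = 1.0   # 1 - noise variance fraction of var(s)

    def s_of_frames(self, frames: FrameSeries) -> np.ndarray:
        """Surrogate values of *new* frames in the fitted units (may lie
        outside [0, 1]; that is exactly the extrapolation case)."""
        return self.transform.normalise(self.transform.score(frames.sinos))

    def end_exhale_mode(self, bins: int = 24) -> float:
        """Histogram mode of s — the long-dwell end-exhale value."""
        hist, edges = np.histogram(self.s, bins=bins)
        i = int(np.argmax(hist))
        return float(0.5 * (edges[i] + edges[i + 1]))


def _axial_com(sinos: np.ndarray) -> np.ndarray:
    """Axial centre-of-mass proxy.

    The radial coordinate at angle theta measures ``-z sin(theta)
    + x cos(theta)``, so the sin-weighted average of per-angle radial
    centres of mass isolates the superior-inferior (z) shift while using
    every recorded count — robust even for sparse sub-second frames."""
    n_angles = sinos.shape[1]
    angles = np.arange(n_angles) * np.pi / n_angles
    r = np.arange(sinos.shape[2], dtype=float)
    tot = sinos.sum(axis=2)                      # (n_frames, n_angles)
    safe = np.where(tot > 0, tot, 1.0)
    com_r = (sinos * r).sum(axis=2) / safe       # per-angle radial COM
    w = np.sin(angles)
    # minus: radial axis runs opposite to z; positive output = inferior shift
    return -(com_r * w).sum(axis=1) / w.sum()


def extract_surrogate(frames: FrameSeries, method: str = "pca",
                      smoothing_s: float = 1.5,
                      rebin: int = 4) -> SurrogateSeries:
    """Derive the respiratory surrogate from the PET frames alone.

    Parameters
    ----------
    frames : FrameSeries
        Short-frame PET data (>= 2 frames).
    method : {"pca", "com"}
        First principal-component score (default) or axial centre of mass.
    rebin : int
        Coarse sinogram rebin factor before the PCA (statistics boost for
        short noisy frames; 1 disables).
    smoothing_s : float
        Savitzky-Golay window (seconds) applied before differentiation.
    """
    if frames.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sinos = frames.sinos
    if not np.any(sinos):
        raise DegenerateSignalError("all frames are zero")

    X = _rebin(sinos, rebin if method == "pca" else 1).reshape(
        frames.n_frames, -1)
    mean = X.mean(axis=0)
    com = _axial_com(sinos)

    if method == "pca":
        Xc = X - mean
        gram = Xc @ Xc.T
        evals, evecs = np.linalg.eigh(gram)
        lead = evals[-1]
        if lead <= 0 or lead < 1e-12 * max(1.0, np.abs(evals).max()):
            raw = np.zeros(frames.n_frames)
            component = np.zeros(X.shape[1])
        else:
            u = evecs[:, -1]
            component = Xc.T @ u / np.sqrt(lead)
            raw = Xc @ component
    elif method == "com":
        raw = com.copy()
        component = np.zeros(X.shape[1])
    else:
        raise ValueError(f"unknown surrogate method {method!r}")

    # deterministic sign: s rises with the inferior shift of counts
    if np.std(raw) > 0 and np.std(com) > 0:
        if np.corrcoef(raw, com)[0, 1] < 0:
            raw = -raw
            component = -component

    # local-polynomial smoothing before normalisation: the raw per-frame
    # score carries Poisson noise that would otherwise dilute every
    # downstream regression on s (errors-in-variables attenuation)
    dt = float(np.median(frames.durations))
    win = max(5, int(round(smoothing_s / dt)) | 1)
    win = min(win, len(raw) - (1 - len(raw) % 2))
    smooth = savgol_filter(raw, win, polyorder=2) if len(raw) >= win >= 5 \
        else raw

    s_min, s_max = float(smooth.min()), float(smooth.max())
    scale = max(np.abs(smooth).max(), 1.0)
    degenerate = (s_max - s_min) <= 1e-9 * scale
    tr = SurrogateTransform(mean=mean, component=component,
                            s_min=s_min, s_max=s_max, method=method,
                            rebin=rebin if method == "pca" else 1)
    if degenerate:
        s = np.zeros(frames.n_frames)
        sdot = np.zeros(frames.n_frames)
        return SurrogateSeries(frames.t_mid, s, sdot, tr, smoothing_s,
                               degenerate=True)

    s = tr.normalise(smooth)
    sdot = np.gradient(s, frames.t_mid)

    # per-frame score noise from the 0.8-1.0 Hz spectral floor (clear of
    # quiet-breathing harmonics); feeds the regression-dilution correction
    # applied when the model is queried at a precisely measured state
    raw_norm = (raw - s_min) / (s_max - s_min)
    spec = np.fft.rfft(raw_norm - raw_norm.mean())
    freq = np.fft.rfftfreq(len(raw_norm), dt)
    band = (freq >= 0.8) & (freq <= 1.0)
    if band.sum() >= 4:
        noise_sd = float(np.sqrt(np.median(np.abs(spec[band]) ** 2)
                                 / len(raw_norm) / np.log(2)))
    else:
        noise_sd = 0.0
    if len(s) >= win >= 5:
        kernel = savgol_coeffs(win, 2)
        smooth_gain = float((kernel ** 2).sum())
    else:
        smooth_gain = 1.0
    var_s = float(np.var(s))
    rel = 1.0 - smooth_gain * noise_sd ** 2 / var_s if var_s > 0 else 1.0
    rel = float(np.clip(rel, 0.5, 1.0))
    return SurrogateSeries(frames.t_mid, s, sdot, tr, smoothing_s,
                           noise_sd=noise_sd, reliability=rel)


# ---------------------------------------------------------------------------
# MR-derived trace and clock alignment
# ---------------------------------------------------------------------------

def mr_diaphragm_trace(mr: DynamicMRSeries,
                       column_band=(0.50, 0.85)) -> np.ndarray:
    """Diaphragm-edge row (mm) per MR image, by subpixel localisation of the
    strongest dark-to-bright vertical transition in a lateral column band
    (the lung/liver boundary)."""
    lo = int(column_band[0] * mr.images.shape[2])
    hi = int(column_band[1] * mr.images.shape[2])
    dz = mr.spacing_mm[0]
    trace = np.empty(mr.n_images)
    for i, img in enumerate(mr.images):
        prof = img[:, lo:hi].mean(axis=1)
        grad = np.gradient(prof)
        j = int(np.argmax(grad))
        # parabolic subpixel refinement
        if 0 < j < len(grad) - 1:
            denom = grad[j - 1] - 2 * grad[j] + grad[j + 1]
            off = 0.5 * (grad[j - 1] - grad[j + 1]) / denom if denom != 0 else 0.0
            off = float(np.clip(off, -0.5, 0.5))
        else:
            off = 0.0
        trace[i] = (j + off) * dz
    return trace


def _standardise_per_position(trace, positions):
    out = np.empty_like(trace)
    for p in np.unique(positions):
        m = positions == p
        mu, sd = trace[m].mean(), trace[m].std()
        out[m] = (trace[m] - mu) / (sd if sd > 0 else 1.0)
    return out


@dataclass
class ClockAlignment:
    """MR->PET clock mapping: t_pet = (t_mr - tau) / rate."""

    tau: float             # time shift, s
    rate: float            # MR/PET clock-rate factor
    objective: float       # correlation at the optimum
    tau_grid: np.ndarray = None
    objective_grid: np.ndarray = None

    def to_pet_time(self, t_mr) -> np.ndarray:
        return (np.asarray(t_mr, dtype=float) - self.tau) / self.rate


def _alignment_objective(surr, trace_std, t_mr, tau, rate):
    t_pet = (t_mr - tau) / rate
    inside = (t_pet >= surr.t[0]) & (t_pet <= surr.t[-1])
    if inside.sum() < 8:
        return -np.inf
    s_i = np.interp(t_pet[inside], surr.t, surr.s)
    z = trace_std[inside]
    if s_i.std() == 0 or z.std() == 0:
        return -np.inf
    return float(np.corrcoef(s_i, z)[0, 1])


def align_clocks(surr: SurrogateSeries, mr: DynamicMRSeries,
                 trace: np.ndarray = None, tau_bound: float = 10.0,
                 tau_step: float = 0.1, estimate_rate: bool = False,
                 rate_halfwidth: float = 2e-4,
                 n_rate: int = 9) -> ClockAlignment:
    """Recover the MR-to-PET time shift by correlation maximisation.

    The MR trace defaults to the diaphragm-edge position per image,
    standardised within each slice position and concatenated in time order.
    A grid search over tau (and optionally the clock-rate factor) is refined
    by a parabolic step around the best grid point.
    """
    if surr.degenerate:
        raise DegenerateSignalError("surrogate is degenerate; cannot align")
    if trace is None:
        trace = mr_diaphragm_trace(mr)
    trace_std = _standardise_per_position(np.asarray(trace, dtype=float),
                                          mr.slice_position)
    if trace_std.std() == 0:
        raise DegenerateSignalError("MR trace is flat; cannot align")

    taus = np.arange(-tau_bound, tau_bound + 0.5 * tau_step, tau_step)
    rates = (np.linspace(1 - rate_halfwidth, 1 + rate_halfwidth, n_rate)
             if estimate_rate else np.array([1.0]))

    best = (-np.inf, taus[0], 1.0, None)
    for rate in rates:
        obj = np.array([_alignment_objective(surr, trace_std, mr.t_mr, tau, rate)
                        for tau in taus])
        k = int(np.argmax(obj))
        if obj[k] > best[0]:
            best = (obj[k], taus[k], float(rate), obj)
    obj_best, tau_best, rate_best, obj_grid = best
    if not np.isfinite(obj_best):
        raise ValueError("acquisition windows do not overlap")

    # parabolic refinement on the tau grid
    k = int(np.argmax(obj_grid))
    if 0 < k < len(taus) - 1 and np.all(np.isfinite(obj_grid[k - 1:k + 2])):
        denom = obj_grid[k - 1] - 2 * obj_grid[k] + obj_grid[k + 1]
        if denom != 0:
            off = 0.5 * (obj_grid[k - 1] - obj_grid[k + 1]) / denom
            tau_ref = taus[k] + float(np.clip(off, -1, 1)) * tau_step
            obj_ref = _alignment_objective(surr, trace_std, mr.t_mr, tau_ref,
                                           rate_best)
            # keep the refinement only if it does not drop below the grid max
            if obj_ref >= obj_best:
                tau_best, obj_best = tau_ref, obj_ref

    return ClockAlignment(tau=float(tau_best), rate=rate_best,
                          objective=float(obj_best), tau_grid=taus,
                          objective_grid=obj_grid)
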