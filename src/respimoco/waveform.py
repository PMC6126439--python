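"""Synthetic breathing waveforms with cycle-to-cycle variability.

The surrogate amplitude ``s`` is dimensionless: 0 is the reference end-exhale
position and 1 the nominal end-inhale of an average cycle.  Each cycle follows
a raised-sine-power template ``s(t) = a_c * sin^{2k}(pi t / T_c)``: the
2k-th-order flat bottom gives the long end-exhale dwell of quiet human
breathing, while end-inhale stays a brief quadratic turn-around.  The
per-cycle amplitude ``a_c`` and period ``T_c`` are drawn independently to
emulate intercycle variation, and an optional slow baseline drift can be
superposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BreathingWaveform", "make_waveform", "template_cycle_mean"]


@dataclass
class BreathingWaveform:
    """Sampled surrogate-amplitude trace s(t) with its time derivative."""

    t: np.ndarray        # sample times, s, strictly increasing
    s: np.ndarray        # surrogate amplitude, a.u. (0 = end-exhale)
    cycle_amplitudes: np.ndarray
    cycle_periods: np.ndarray
    drift: float = 0.0   # a.u. per minute

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.t.ndim != 1 or self.t.size != self.s.size:
            raise ValueError("t and s must be 1D and equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.s))):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def s_at(self, times) -> np.ndarray:
        """Linear interpolation of s at arbitrary times within the window."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.s)

    def sdot_at(self, times) -> np.ndarray:
        """Time derivative of s (a.u./s) at arbitrary times."""
        sdot = np.gradient(self.s, self.t)
        return np.interp(np.asarray(times, dtype=float), self.t, sdot)


def template_cycle_mean(k: int = 2) -> float:
    """Closed-form cycle mean of the unit template sin^{2k}(pi t / T):
    C(2k, k) / 4^k."""
    from math import comb
    return comb(2 * k, k) / 4.0 ** k


def make_waveform(duration: float = 240.0, mean_period: float = 4.0,
                  period_cv: float = 0.1, mean_amplitude: float = 1.0,
                  amplitude_cv: float = 0.15, k: int = 2,
                  drift_per_min: float = 0.0, dt: float = 0.05,
                  seed: int | np.random.Generator = 0) -> BreathingWaveform:
    """Generate a breathing waveform covering ``duration`` seconds.

    Parameters
    ----------
    duration, mean_period : float
        Acquisition window and mean breathing period, s (defaults: 4-min
        window, 4-s quiet-breathing cycle).
    period_cv, amplitude_cv : float
        Coefficients of variation of the per-cycle period and amplitude
        draws (intercycle variability; 15% amplitude CV by default).
    k : int
        Template sharpness; larger k lengthens the end-exhale dwell.
    drift_per_min : float
        Linear baseline drift in surrogate units per minute (0 = off).
    dt : float
        Sample step, s.
    seed : int or Generator
        RNG seed for the per-cycle draws.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if mean_period <= 0:
        raise ValueError("mean period must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)

    periods, amplitudes = [], []
    total = 0.0
    while total < duration:
        T = max(0.5 * mean_period,
                rng.normal(mean_period, period_cv * mean_period))
        a = max(0.0, rng.normal(mean_amplitude, amplitude_cv * abs(mean_amplitude))) \
            if mean_amplitude != 0 else 0.0
        periods.append(T)
        amplitudes.append(a)
        total += T

    t = np.arange(0.0, duration + 0.5 * dt, dt)
    s = np.zeros_like(t)
    start = 0.0
    for T, a in zip(periods, amplitudes):
        in_cycle = (t >= start) & (t < start + T)
        phase = (t[in_cycle] - start) / T
        s[in_cycle] = a * np.sin(np.pi * phase) ** (2 * k)
        start += T
    if drift_per_min:
        s = s + drift_per_min * t / 60.0
    return BreathingWaveform(t, s, np.asarray(amplitudes),
                             np.asarray(periods), drift_per_min)
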