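"""Self-contained validation experiments on the synthetic phantom.

Each function sets up a study condition — breathing phantom, acquisition,
correction — runs the relevant part of the pipeline from scratch, and
returns the measured quantities as a plain dict.  The experiments double as
the package's quantitative regression checks: the test suite asserts on
them, and ``scripts/acceptance.py`` reports them.

Problem sizes follow the package defaults (128 x 128 coronal slab at 3 mm,
126 projection angles, 4-min PET window at 0.5-s frames, 1-min dynamic MR at
0.3 s/image); the direction-of-effect study amortises the motion-free
reference by Poisson-resampling one precomputed noise-free acquisition.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats as sps
from scipy.ndimage import binary_dilation

from .acquisition import (acquire_breathhold_frames, acquire_dynamic_mr,
                          acquire_mumap, acquire_pet)
from .grids import VoxelVolume
from .motionmodel import MotionModel, MotionModelResult
from .phantom import build_phantom, default_spec, make_motion
from .projector import get_projector
from .quantify import paired_t, suv_max, suv_peak, suv_scale, \
    wilcoxon_signed_rank
from .recon import ReconSettings, make_gates, osem, recon_motion_corrected, \
    recon_uncorrected
from .registration import register_slices
from .surrogate import SurrogateSeries, SurrogateTransform, align_clocks, \
    extract_surrogate
from .waveform import make_waveform

__all__ = [
    "parameter_recovery", "null_recovery", "hysteresis_advantage",
    "time_shift_recovery", "gating_conservation", "osem_consistency",
    "suv_oracle_agreement", "direction_of_effect", "mumap_artifact_reduction",
    "stats_oracle_agreement",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _seeds(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def truth_model(motion) -> MotionModelResult:
    """Motion-model result holding the generator's own coefficients —
    the 'true model given, skip fitting' validation mode."""
    coef = np.stack([motion.g0, motion.g1, motion.g2])
    like = np.ones_like(motion.g1)
    return MotionModelResult(coef=coef, term_names=("const", "s", "sdot"),
                             spacing_mm=motion.spacing, r_squared=like,
                             weight_sum=like, n_obs=0, n_excluded=0,
                             s_range=(0.0, 1.5), sdot_range=(-2.0, 2.0),
                             ref_state=(0.0, 0.0), robust="truth")


def truth_surrogate(frames) -> SurrogateSeries:
    """Surrogate series carrying the simulator's hidden truth (for the
    skip-fitting validation mode only)."""
    tr = SurrogateTransform(np.zeros(1), np.zeros(1), 0.0, 1.0, "truth")
    return SurrogateSeries(frames.t_mid, frames.hidden_s,
                           frames.hidden_sdot, tr, 0.0)


def _default_setup(lesion_diameter_mm=10.0, excursion_mm=20.0,
                   hysteresis_mm_s=2.0, mismatch_mm=0.0):
    spec = default_spec(lesion_diameter_mm=lesion_diameter_mm)
    ph = build_phantom(spec)
    mot = make_motion(ph, excursion_mm=excursion_mm,
                      hysteresis_mm_s=hysteresis_mm_s,
                      mismatch_mm=mismatch_mm)
    return spec, ph, mot


# ---------------------------------------------------------------------------
# 1. motion-model parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery(seed: int = 0, n_images: int = 200,
                       noise_mm: float = 0.5) -> dict:
    """Fit the 2-surrogate model to displacements generated from known
    linear coefficients plus Gaussian noise, and measure coefficient errors.

    Truth: the phantom's motion generator (c1 up to the 20-mm diaphragm
    excursion, c2 the hysteresis term) plus a 2-mm constant offset.
    """
    _, ph, mot = _default_setup()
    rng = np.random.default_rng(seed)
    wave = make_waveform(duration=n_images * 0.3, seed=rng.integers(2**31))
    t = (np.arange(n_images) + 0.5) * 0.3
    s, sdot = wave.s_at(t), wave.sdot_at(t)

    c0_true = np.zeros_like(mot.g1)
    c0_true[0] = 2.0
    fields = (c0_true[None] + mot.g1[None] * s[:, None, None, None]
              + mot.g2[None] * sdot[:, None, None, None])
    fields = fields + rng.normal(0.0, noise_mm, fields.shape)

    res = MotionModel(fields=fields, s=s, sdot=sdot,
                      spacing_mm=mot.spacing).fit()
    err_c1 = res.c1 - mot.g1
    err_c0 = res.c0 - c0_true
    big = np.abs(mot.g1) >= 2.0
    rel = np.abs(err_c1[big]) / np.abs(mot.g1[big])
    return {
        "c1_mean_rel_err_pct": float(100 * rel.mean()),
        "c1_median_rel_err_pct": float(100 * np.median(rel)),
        "c1_max_rel_err_pct": float(100 * rel.max()),
        "c0_mean_abs_err_mm": float(np.abs(err_c0).mean()),
        "c0_max_abs_err_mm": float(np.abs(err_c0).max()),
        "n_images": n_images,
    }


# ---------------------------------------------------------------------------
# 2. null recovery (motionless acquisition)
# ---------------------------------------------------------------------------

def null_recovery(seed: int = 0) -> dict:
    """Motionless acquisition: the fitted model must be (near) null and the
    motion-corrected reconstruction must equal the uncorrected one.

    Noisy branch: PET/MR noise only -> fitted |c1|, |c2| stay small.
    Noiseless branch: no signal at all -> the surrogate is degenerate, the
    pipeline falls back to the null model, and MC == U to float precision.
    """
    s_wave, s_pet, s_mr = _seeds(seed, 3)
    spec, ph, mot = _default_setup()
    still = make_waveform(240.0, mean_amplitude=0.0, amplitude_cv=0.0,
                          seed=s_wave)

    # --- noisy branch: model null recovery
    frames = acquire_pet(ph.activity, ph.mu, mot, still, noise=True,
                         seed=s_pet)
    mr = acquire_dynamic_mr(ph, mot, still, start_time=180.0, seed=s_mr)
    surr = extract_surrogate(frames)
    t_img = mr.hidden_t_pet
    s_img = np.interp(t_img, surr.t, surr.s)
    reg = register_slices(mr, s_images=s_img)
    sdot_img = np.interp(t_img, surr.t, surr.sdot)
    model = MotionModel(fields=reg.fields, s=s_img, sdot=sdot_img,
                        spacing_mm=reg.spacing_mm,
                        exclude=reg.outlier).fit()

    # --- noiseless branch: MC == U through the degenerate-signal path
    frames0 = acquire_pet(ph.activity, ph.mu, mot, still, noise=False,
                          seed=s_pet)
    surr0 = extract_surrogate(frames0)
    assert surr0.degenerate, "noiseless motionless data must be degenerate"
    null_model = MotionModelResult.zero(ph.activity.shape,
                                        ph.activity.spacing)
    mumap = acquire_mumap(ph.mu, mot, (0.0, 0.0))
    proj = get_projector(ph.activity.shape, ph.activity.spacing,
                         frames0.n_angles)
    settings = ReconSettings(21, 3, 4.0)
    u = recon_uncorrected(frames0, mumap, settings, proj)
    gates = make_gates(surr0, frames0, 8)
    mc = recon_motion_corrected(
        frames0, mumap, null_model, gates,
        ReconSettings(21, 3, 4.0, mode="motion-corrected"), proj,
        mu_state=(0.0, 0.0))
    denom = max(np.abs(u.values).max(), 1e-30)
    rel = float(np.abs(mc.values - u.values).max() / denom)
    return {
        "max_abs_c1_mm": float(np.abs(model.c1).max()),
        "max_abs_c2_mm": float(np.abs(model.c2).max()),
        "mc_vs_u_max_rel_diff": rel,
    }


# ---------------------------------------------------------------------------
# 3. hysteresis advantage of the 2-surrogate model
# ---------------------------------------------------------------------------

def hysteresis_advantage(seed: int = 0, n_seeds: int = 5,
                         noise_mm: float = 0.5) -> dict:
    """With hysteretic ground truth (gradient term active), the 2-surrogate
    model must out-predict the best amplitude-only model on fresh states."""
    _, ph, mot = _default_setup()          # hysteresis 2 mm*s by default
    ratios = []
    for child in _seeds(seed, n_seeds):
        rng = np.random.default_rng(child)
        wave = make_waveform(60.0, seed=rng.integers(2**31))
        t = (np.arange(200) + 0.5) * 0.3
        s, sdot = wave.s_at(t), wave.sdot_at(t)
        fields = (mot.g1[None] * s[:, None, None, None]
                  + mot.g2[None] * sdot[:, None, None, None])
        fields = fields + rng.normal(0.0, noise_mm, fields.shape)
        data = MotionModel(fields=fields, s=s, sdot=sdot,
                           spacing_mm=mot.spacing)
        m2 = data.fit(surrogates=("s", "sdot"))
        m1 = data.fit(surrogates=("s",))

        test_wave = make_waveform(40.0, seed=rng.integers(2**31))
        tt = (np.arange(100) + 0.5) * 0.4
        errs2, errs1 = [], []
        for sv, sd in zip(test_wave.s_at(tt), test_wave.sdot_at(tt)):
            truth = mot.motion_at(sv, sd).data
            errs2.append(np.abs(m2.predict_field(sv, sd).data - truth).mean())
            errs1.append(np.abs(m1.predict_field(sv, sd).data - truth).mean())
        ratios.append(float(np.mean(errs2) / np.mean(errs1)))
    return {
        "error_ratio_2s_over_1s": ratios,
        "max_error_ratio": float(max(ratios)),
        "all_seeds_improved": bool(all(r < 1.0 for r in ratios)),
    }


# ---------------------------------------------------------------------------
# 4. PET/MR time-shift recovery
# ---------------------------------------------------------------------------

def time_shift_recovery(seed: int = 0,
                        taus=(-5.0, -2.0, 0.0, 2.0, 5.0)) -> dict:
    """Inject known MR clock offsets and recover them from the data."""
    s_wave, s_pet, s_mr = _seeds(seed, 3)
    _, ph, mot = _default_setup()
    wave = make_waveform(240.0, seed=s_wave)
    frames = acquire_pet(ph.activity, ph.mu, mot, wave, noise=True,
                         seed=s_pet)
    surr = extract_surrogate(frames)
    errors = {}
    for tau in taus:
        mr = acquire_dynamic_mr(ph, mot, wave, start_time=180.0,
                                clock_offset=tau, seed=s_mr)
        align = align_clocks(surr, mr)
        errors[tau] = float(align.tau - tau)
    return {
        "tau_errors_s": errors,
        "max_abs_tau_error_s": float(max(abs(e) for e in errors.values())),
    }


# ---------------------------------------------------------------------------
# 5. gating count conservation
# ---------------------------------------------------------------------------

def gating_conservation(seed: int = 0, n_gates: int = 8) -> dict:
    """Counts must partition exactly over gates, and the MC reconstruction
    must consume every frame."""
    s_wave, s_pet = _seeds(seed, 2)
    _, ph, mot = _default_setup()
    wave = make_waveform(240.0, seed=s_wave)
    frames = acquire_pet(ph.activity, ph.mu, mot, wave, noise=True,
                         seed=s_pet)
    surr = extract_surrogate(frames)
    gates = make_gates(surr, frames, n_gates)
    per_gate = [frames.pooled(gates.frames_in(g))[0].sum()
                for g in range(gates.n_gates)]
    discrepancy = float(abs(sum(per_gate) - frames.total_counts))
    frames_used = int(sum(gates.gate_sizes))
    return {
        "count_discrepancy": discrepancy,
        "frames_used_fraction": frames_used / frames.n_frames,
        "total_counts": frames.total_counts,
    }


# ---------------------------------------------------------------------------
# 6. OSEM self-consistency
# ---------------------------------------------------------------------------

def osem_consistency(seed: int = 0) -> dict:
    """Noiseless static data: 21x3 OSEM must fit its own data (low NRMSE,
    nonincreasing per subiteration) and 1-subset OSEM must equal MLEM."""
    _, ph, mot = _default_setup()
    still = make_waveform(20.0, mean_amplitude=0.0, amplitude_cv=0.0,
                          seed=seed)
    frames = acquire_pet(ph.activity, ph.mu, mot, still, noise=False,
                         duration=20.0)
    mumap = acquire_mumap(ph.mu, mot, (0.0, 0.0))
    proj = get_projector(ph.activity.shape, ph.activity.spacing,
                         frames.n_angles)
    img = recon_uncorrected(frames, mumap, ReconSettings(21, 3, 4.0), proj,
                            track_nrmse=True)
    nrmse = img.nrmse_per_subiteration

    sino, bkg, live = frames.pooled()
    atten = proj.attenuation_factors(mumap.mu.values)
    scale = frames.calibration * live
    o1 = osem(sino, atten, ReconSettings(1, 12, 0.0), proj, scale=scale,
              background=bkg)
    # independent plain-MLEM loop with the same operators
    x = np.ones(proj.shape)
    sens = scale * proj.back(atten)
    m = sens > 0
    x[~m] = 0.0
    for _ in range(12):
        ybar = scale * atten * proj.forward(x) + bkg
        ratio = np.where(sino > 0, sino / np.maximum(ybar, 1e-30), 0.0)
        bp = scale * proj.back(atten * ratio)
        x[m] *= bp[m] / sens[m]
    mlem_rel = float(np.abs(o1.unfiltered - x).max() / x.max())
    return {
        "final_nrmse_pct": float(100 * nrmse[-1]),
        "monotone_nonincreasing": bool(np.all(np.diff(nrmse) <= 1e-12)),
        "osem1_vs_mlem_max_rel_diff": mlem_rel,
    }


# ---------------------------------------------------------------------------
# 7. SUV metrics vs brute-force sweeps
# ---------------------------------------------------------------------------

def _suv_peak_bruteforce(vol: VoxelVolume, roi, diameter_mm) -> float:
    """Independent exhaustive sweep: loop over ROI centres, mean over an
    explicitly constructed in-grid sphere."""
    r = diameter_mm / 2.0
    spacing = vol.spacing
    best = -np.inf
    for center in np.argwhere(roi):
        half = [int(np.floor(r / s)) for s in spacing]
        sl, offs = [], []
        ranges = [range(max(0, c - h), min(n, c + h + 1))
                  for c, h, n in zip(center, half, vol.shape)]
        vals = []
        for idx in product(*ranges):
            d2 = sum(((i - c) * s) ** 2
                     for i, c, s in zip(idx, center, spacing))
            if d2 <= r ** 2:
                vals.append(vol.values[idx])
        best = max(best, float(np.mean(vals)))
    return best


def suv_oracle_agreement(seed: int = 0, n_volumes: int = 20) -> dict:
    """suv_peak / suv_max vs exhaustive brute force on random volumes."""
    rng = np.random.default_rng(seed)
    max_diff_peak = 0.0
    max_diff_max = 0.0
    for _ in range(n_volumes):
        n = int(rng.integers(20, 41))
        vol = VoxelVolume(rng.random((n, n, n)), (3.0, 3.0, 3.0),
                          semantics="suv")
        roi = np.zeros((n, n, n), dtype=bool)
        c = rng.integers(5, n - 5, size=3)
        roi[c[0]-2:c[0]+3, c[1]-2:c[1]+3, c[2]-2:c[2]+3] = True
        got = suv_peak(vol, roi, 12.0)
        want = _suv_peak_bruteforce(vol, roi, 12.0)
        max_diff_peak = max(max_diff_peak, abs(got - want))
        got_m = suv_max(vol, roi)
        want_m = float(max(vol.values[tuple(i)] for i in np.argwhere(roi)))
        max_diff_max = max(max_diff_max, abs(got_m - want_m))
    return {"suv_peak_max_abs_diff": max_diff_peak,
            "suv_max_max_abs_diff": max_diff_max,
            "n_volumes": n_volumes}


# ---------------------------------------------------------------------------
# 8. direction of effect: MC recovers lesion uptake
# ---------------------------------------------------------------------------

def direction_of_effect(seed: int = 0, n_runs: int = 20) -> dict:
    """Moving 10-mm lesion, 20-mm diaphragm excursion: motion correction
    must raise SUV_peak over the uncorrected image and land near the
    motion-free reconstruction.

    Uses the generator's own model and surrogate (skip-fitting validation
    mode) so the comparison isolates the reconstruction machinery.
    """
    spec, ph, mot = _default_setup()
    mot0 = make_motion(ph, excursion_mm=0.0, hysteresis_mm_s=0.0)
    proj = get_projector(ph.activity.shape, ph.activity.spacing, 126)
    mumap = acquire_mumap(ph.mu, mot, (0.0, 0.0))
    model = truth_model(mot)
    settings_u = ReconSettings(21, 3, 4.0)
    settings_mc = ReconSettings(21, 3, 4.0, mode="motion-corrected")
    roi = binary_dilation(ph.lesion_masks[0], iterations=3)
    w, d = spec.weight_kg, spec.dose_MBq

    # the motion-free reference is the noise-free motionless acquisition's
    # reconstruction: a deterministic target, so per-seed deviations measure
    # the motion-corrected image alone
    still = make_waveform(240.0, mean_amplitude=0.0, amplitude_cv=0.0,
                          seed=0)
    mf_expected = acquire_pet(ph.activity, ph.mu, mot0, still, noise=False)
    mumap0 = acquire_mumap(ph.mu, mot0, (0.0, 0.0))
    mf = recon_uncorrected(mf_expected, mumap0, settings_u, proj)
    pk_mf = suv_peak(suv_scale(mf.volume, w, d), roi)

    deltas, mf_devs = [], []
    for child in _seeds(seed, n_runs):
        s_wave, s_pet = child.spawn(2)
        wave = make_waveform(240.0, seed=s_wave)
        frames = acquire_pet(ph.activity, ph.mu, mot, wave, noise=True,
                             seed=s_pet)
        surr = truth_surrogate(frames)
        u = recon_uncorrected(frames, mumap, settings_u, proj)
        gates = make_gates(surr, frames, 8)
        mc = recon_motion_corrected(frames, mumap, model, gates,
                                    settings_mc, proj, mu_state=(0.0, 0.0))
        pk_u = suv_peak(suv_scale(u.volume, w, d), roi)
        pk_mc = suv_peak(suv_scale(mc.volume, w, d), roi)
        deltas.append(100.0 * (pk_mc - pk_u) / pk_u)
        mf_devs.append(100.0 * abs(pk_mc - pk_mf) / pk_mf)
    deltas = np.asarray(deltas)
    return {
        "fraction_delta_positive": float((deltas > 0).mean()),
        "mean_delta_suv_peak_pct": float(deltas.mean()),
        "max_mc_vs_motionfree_dev_pct": float(max(mf_devs)),
        "motion_free_suv_peak": pk_mf,
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# 9. attenuation-map misalignment artifact reduction
# ---------------------------------------------------------------------------

def mumap_artifact_reduction(seed: int = 0, mu_state_s: float = 1.2) -> dict:
    """Deep-inhale attenuation map: the uncorrected image shows a
    negative-bias band at the diaphragm; the fitted model's warped maps must
    largely remove it.

    Runs the *full* fitted pipeline (surrogate, alignment, registration,
    model) — the map's surrogate value comes from the breath-hold PET
    segment, and correcting it requires extrapolating the model beyond the
    free-breathing range.
    """
    s_wave, s_pet, s_mr, s_bh = _seeds(seed, 4)
    spec, ph, mot = _default_setup()
    wave = make_waveform(240.0, seed=s_wave)
    frames = acquire_pet(ph.activity, ph.mu, mot, wave, noise=True,
                         seed=s_pet)
    mr = acquire_dynamic_mr(ph, mot, wave, start_time=180.0, seed=s_mr)
    mumap = acquire_mumap(ph.mu, mot, (mu_state_s, 0.0))
    mumap.surrogate_frames = acquire_breathhold_frames(
        ph.activity, ph.mu, mot, (mu_state_s, 0.0),
        calibration=frames.calibration, seed=s_bh)

    surr = extract_surrogate(frames)
    align = align_clocks(surr, mr)
    t_img = align.to_pet_time(mr.t_mr)
    s_img = np.interp(t_img, surr.t, surr.s)
    reg = register_slices(mr, s_images=s_img)
    model = MotionModel.from_registration(reg, surr, align, mr).fit()

    proj = get_projector(ph.activity.shape, ph.activity.spacing,
                         frames.n_angles)
    settings = ReconSettings(21, 3, 4.0)
    u = recon_uncorrected(frames, mumap, settings, proj)
    gates = make_gates(surr, frames, 8)
    mc = recon_motion_corrected(frames, mumap, model, gates,
                                ReconSettings(21, 3, 4.0,
                                              mode="motion-corrected"),
                                proj, surr=surr)

    # local truth: motion-free reconstruction with the correct map
    still = make_waveform(240.0, mean_amplitude=0.0, amplitude_cv=0.0,
                          seed=0)
    mot0 = make_motion(ph, excursion_mm=0.0, hysteresis_mm_s=0.0)
    frames0 = acquire_pet(ph.activity, ph.mu, mot0, still, noise=False)
    truth = recon_uncorrected(frames0, acquire_mumap(ph.mu, mot0, (0, 0)),
                              settings, proj)

    # diaphragm band ROI: +-9 mm around the diaphragm, right-lung columns
    nz, nx = ph.activity.shape
    dz = ph.activity.spacing[0]
    z0 = int(round(ph.diaphragm_z_mm / dz))
    band = np.zeros((nz, nx), dtype=bool)
    band[max(0, z0 - 3):z0 + 4, int(0.52 * nx):int(0.84 * nx)] = True
    band &= ph.body_mask

    tmean = truth.values[band].mean()
    bias_u = u.values[band] - truth.values[band]
    bias_mc = mc.values[band] - truth.values[band]
    return {
        "u_mean_bias_pct_of_truth": float(100 * bias_u.mean() / tmean),
        "u_mean_abs_bias_pct": float(100 * np.abs(bias_u).mean() / tmean),
        "mc_mean_abs_bias_pct": float(100 * np.abs(bias_mc).mean() / tmean),
        "abs_bias_reduction_pct": float(
            100 * (1 - np.abs(bias_mc).mean() / np.abs(bias_u).mean())),
        "mu_state_estimated_s": mc.provenance["mu_state"][0],
    }


# ---------------------------------------------------------------------------
# 10. statistical-test oracles
# ---------------------------------------------------------------------------

def _wilcoxon_exact_bruteforce(d: np.ndarray) -> float:
    """Two-sided exact p by explicit iteration over all sign assignments."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    ws = []
    for signs in product([0, 1], repeat=m):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def stats_oracle_agreement(seed: int = 0) -> dict:
    """Exact Wilcoxon vs full enumeration (m <= 12), the normal
    approximation vs exact at m = 12, and the paired t vs an independent
    implementation."""
    rng = np.random.default_rng(seed)
    max_exact_diff = 0.0
    for m in range(3, 13):
        for _ in range(3):
            before = rng.integers(0, 5, m)
            after = before + rng.integers(-2, 3, m)
            d = (after - before).astype(float)
            if np.all(d == 0):
                continue
            _, p = wilcoxon_signed_rank(before, after, mode="exact")
            p_ref = _wilcoxon_exact_bruteforce(d)
            max_exact_diff = max(max_exact_diff, abs(p - p_ref))

    max_approx_diff = 0.0
    for _ in range(20):
        before = rng.normal(0, 1, 12)
        after = before + rng.normal(0.3, 1, 12)
        _, p_e = wilcoxon_signed_rank(before, after, mode="exact")
        _, p_a = wilcoxon_signed_rank(before, after, mode="approx")
        max_approx_diff = max(max_approx_diff, abs(p_e - p_a))

    max_t_diff = 0.0
    for _ in range(10):
        u = rng.normal(0, 1, 20)
        mc = u + rng.normal(0.2, 1, 20)
        _, p = paired_t(u, mc)
        p_ref = float(sps.ttest_rel(mc, u).pvalue)
        max_t_diff = max(max_t_diff, abs(p - p_ref))
    return {
        "wilcoxon_exact_max_abs_diff": max_exact_diff,
        "wilcoxon_approx_vs_exact_max_abs_diff": max_approx_diff,
        "paired_t_max_abs_diff": max_t_diff,
    }
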