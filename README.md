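# respimoco

Surrogate-driven respiratory motion correction for simultaneous PET/MR, at
desk scale.

Respiration moves the diaphragm by ~20 mm per breathing cycle. Over a
multi-minute PET acquisition this blurs thoracic and abdominal lesions
(raising their apparent size and lowering their apparent uptake, i.e.
SUV_peak and SUV_max), mislocates lesions at the lung–liver boundary, and —
because the attenuation map is a breath-hold snapshot — produces
emission/attenuation mismatch artifacts such as the dark curved band at the
liver dome. `respimoco` implements, end to end on a synthetic breathing
thorax phantom with known ground-truth motion, a correction pipeline that
needs no external respiratory hardware:

1. **Surrogate**: a respiratory signal s(t) and its gradient ṡ(t) derived
   from the time-binned PET data alone (first principal-component score of
   the frame sinograms), with PET/MR clock alignment by time-shift
   optimisation against a diaphragm trace from a 1-min free-breathing
   dynamic MR acquisition (9 slice positions, 0.3 s/image).
2. **Motion model**: per-voxel robust (Huber IRLS) linear fit

       d(x; s, ṡ) = c0(x) + c1(x)·s + c2(x)·ṡ   [mm]

   of the MR-registration displacement fields on the two surrogates. The
   gradient term captures hysteresis (inspiration/expiration path
   difference); the continuous form interpolates and extrapolates to *any*
   respiratory state, so 100% of the PET data are used and the breath-hold
   attenuation map can be mapped between states.
3. **Reconstruction**: OSEM (21 subsets, 3 iterations, 4-mm Gaussian
   postfilter) in uncorrected mode (all data pooled, static μ-map) and
   motion-compensated mode (amplitude gating, per-gate model-warped μ-maps,
   warps with exact adjoints inside the system model, one image estimate at
   the reference state).
4. **Evaluation**: lesion SUV_peak (12-mm sphere) and SUV_max, ΔSUV between
   modes, reader-score (χ, 1–4 confidence) analytics with TP/FP/
   false-negative rules, exact Wilcoxon signed-rank and paired t tests.

The scientific background, model assumptions, parameter choices and known
limitations are documented in [docs/methods.md](docs/methods.md).

## Worked example

Run the end-to-end experiment in which the attenuation map is accidentally
acquired at a deep inhale (s = 1.2, outside the free-breathing range) — the
scenario that produces both lesion blur and the attenuation-mismatch band:

```bash
respimoco run --preset mumap-misalignment --seed 5 --out runs/deep-inhale
```

or equivalently from Python:

```python
from respimoco import run_experiment, validate_config
cfg = validate_config({}, preset="mumap-misalignment")
report = run_experiment(cfg, "runs/deep-inhale", seed=5)
```

Output (abridged from `runs/deep-inhale/report.json`):

```
[simulate]   n_frames: 480, total_counts: 3299192, n_mr_images: 200
[surrogate]  degenerate: False, tau_s: -0.003, objective: 0.967
[fit-model]  mean_abs_c1_mm: 7.38, mean_abs_c2_mm: 0.07, n_obs: 200
[recon]      n_gates: 8, counts_used_mc: 3299192
[evaluate]   lesion 0: SUV_peak 1.14 (U) -> 1.52 (MC)  [+33.1%]
             SUV_max  1.49 (U) -> 2.18 (MC)  [+45.8%]  considerable: True
```

Reading this: the pipeline recovered the PET/MR clock shift (τ ≈ −0.003 s —
none was injected) with a 0.97 alignment correlation, fitted a motion model
whose amplitude coefficient averages 7.4 mm over the grid (peaking at the
20-mm diaphragm excursion, expressed in surrogate units), and used every
acquired count in the motion-compensated reconstruction. Motion correction
raised the liver lesion's SUV_peak by 33% and SUV_max by 46% — a
"considerable" change (> 5% in both metrics); the large magnitudes reflect
the combined recovery from motion blur *and* the deliberately misaligned
attenuation map. All intermediates (NIfTI volumes, frame CSVs, the resolved
config, the model summary) are persisted beside the report; the same config
and seed reproduce the report byte for byte.

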