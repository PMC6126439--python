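"""Serialization: NIfTI volumes, CSV/JSON sidecars, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import VoxelVolume
from .acquisition import FrameSeries, DynamicMRSeries

__all__ = ["save_volume", "load_volume", "save_frames", "load_frames",
           "save_mr_series", "load_mr_series", "save_model", "load_model",
           "save_json", "load_json"]


def _affine(spacing, origin, ndim):
    aff = np.eye(4)
    for a in range(min(ndim, 3)):
        aff[a, a] = spacing[a]
        aff[a, 3] = origin[a]
    return aff


def save_volume(vol: VoxelVolume, path) -> Path:
    """Write a VoxelVolume as NIfTI (spacing in the header, semantics in the
    description field)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64),
                          _affine(vol.spacing, vol.origin, vol.ndim))
    img.header["descrip"] = vol.semantics.encode()[:79]
    nib.save(img, str(path))
    return path


def load_volume(path, semantics: str = None) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = tuple(float(abs(aff[a, a])) for a in range(data.ndim))
    origin = tuple(float(aff[a, 3]) for a in range(data.ndim))
    if semantics is None:
        semantics = img.header["descrip"].tobytes().split(b"\x00")[0].decode() \
            or "generic"
    return VoxelVolume(data, spacing, origin, semantics)


def save_frames(frames: FrameSeries, outdir) -> Path:
    """FrameSeries as a NIfTI sinogram stack + frames.csv + meta.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(frames.sinos.astype(np.float64), np.eye(4)),
             str(outdir / "sinograms.nii.gz"))
    pd.DataFrame({
        "start_s": frames.t_start,
        "duration_s": frames.durations,
        "background_per_bin": frames.background,
        "counts": frames.frame_counts,
    }).to_csv(outdir / "frames.csv", index=False)
    save_json({"calibration": frames.calibration, "noisy": frames.noisy,
               "spacing_mm": frames.spacing_mm, "n_angles": frames.n_angles},
              outdir / "meta.json")
    return outdir


def load_frames(outdir) -> FrameSeries:
    outdir = Path(outdir)
    sinos = np.asarray(nib.load(str(outdir / "sinograms.nii.gz")).dataobj)
    tab = pd.read_csv(outdir / "frames.csv")
    meta = load_json(outdir / "meta.json")
    return FrameSeries(sinos=sinos, t_start=tab["start_s"].to_numpy(),
                       durations=tab["duration_s"].to_numpy(),
                       background=tab["background_per_bin"].to_numpy(),
                       calibration=meta["calibration"], noisy=meta["noisy"],
                       spacing_mm=meta["spacing_mm"],
                       n_angles=meta["n_angles"])


class _NpEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NpEncoder)
                    + "\n")
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def save_mr_series(mr: DynamicMRSeries, outdir) -> Path:
    """DynamicMRSeries as a NIfTI image stack + timing CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mr.images.astype(np.float64), np.eye(4)),
             str(outdir / "mr_stack.nii.gz"))
    pd.DataFrame({"t_mr_s": mr.t_mr,
                  "slice_position": mr.slice_position}).to_csv(
        outdir / "timing.csv", index=False)
    save_json({"n_positions": mr.n_positions,
               "image_duration_s": mr.image_duration,
               "spacing_mm": list(mr.spacing_mm)}, outdir / "meta.json")
    return outdir


def load_mr_series(outdir) -> DynamicMRSeries:
    outdir = Path(outdir)
    images = np.asarray(nib.load(str(outdir / "mr_stack.nii.gz")).dataobj)
    tab = pd.read_csv(outdir / "timing.csv")
    meta = load_json(outdir / "meta.json")
    return DynamicMRSeries(images=images,
                           slice_position=tab["slice_position"].to_numpy(),
                           t_mr=tab["t_mr_s"].to_numpy(),
                           n_positions=meta["n_positions"],
                           image_duration=meta["image_duration_s"],
                           spacing_mm=tuple(meta["spacing_mm"]))


def save_model(model, outdir) -> Path:
    """MotionModelResult as multi-channel NIfTI (one volume per term and
    displacement component) + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(model.coef.astype(np.float64), np.eye(4)),
             str(outdir / "coefficients.nii.gz"))
    nib.save(nib.Nifti1Image(model.r_squared.astype(np.float64), np.eye(4)),
             str(outdir / "r_squared.nii.gz"))
    save_json({"term_names": list(model.term_names),
               "spacing_mm": list(model.spacing_mm),
               "n_obs": model.n_obs, "n_excluded": model.n_excluded,
               "s_range": list(model.s_range),
               "sdot_range": list(model.sdot_range),
               "ref_state": list(model.ref_state),
               "robust": model.robust}, outdir / "model.json")
    (outdir / "summary.txt").write_text(model.summary() + "\n")
    return outdir


def load_model(outdir):
    from .motionmodel import MotionModelResult
    outdir = Path(outdir)
    coef = np.asarray(nib.load(str(outdir / "coefficients.nii.gz")).dataobj)
    r2 = np.asarray(nib.load(str(outdir / "r_squared.nii.gz")).dataobj)
    meta = load_json(outdir / "model.json")
    return MotionModelResult(coef=coef,
                             term_names=tuple(meta["term_names"]),
                             spacing_mm=tuple(meta["spacing_mm"]),
                             r_squared=r2, weight_sum=np.zeros_like(r2),
                             n_obs=meta["n_obs"],
                             n_excluded=meta["n_excluded"],
                             s_range=tuple(meta["s_range"]),
                             sdot_range=tuple(meta["sdot_range"]),
                             ref_state=tuple(meta["ref_state"]),
                             robust=meta["robust"])
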