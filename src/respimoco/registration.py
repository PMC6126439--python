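"""Nonrigid registration of the dynamic MR images to a reference state.

Each slice position gets its own reference image — the image whose surrogate
value is closest to the end-exhale histogram mode (the long-dwell state) —
and every other image at that position is registered to it with a
multi-resolution demons algorithm (SimpleITK).  The output fields use the
package-wide pull-back convention: ``I_t(x) ~= I_ref(x + d_t(x))``, so each
field maps the reference image onto the instantaneous image, matching the
sign of the ground-truth generator.

Images whose post-registration residual is grossly out of line are flagged
as outliers and excluded from the model fit rather than failing the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .acquisition import DynamicMRSeries
from .grids import DisplacementField, warp_array

__all__ = ["RegistrationResult", "register_pair", "register_slices"]


def _to_sitk(arr: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    return img


DEFAULT_LEVELS = ((4, 80), (2, 60), (1, 30))


def register_pair(fixed: np.ndarray, moving: np.ndarray, spacing,
                  levels=DEFAULT_LEVELS, smoothing_sigma: float = 1.5,
                  update_sigma: float = 2.0, presmooth: float = 0.8,
                  intensity_threshold: float = 0.05) -> np.ndarray:
    """Demons registration of ``moving`` onto ``fixed``.

    Returns the pull-back displacement field (mm), shape ``(2, nz, nx)``,
    such that sampling ``moving`` at ``x + d(x)`` reproduces ``fixed``.

    Three-level multi-resolution (shrink 4/2/1) so demons can track
    multi-voxel diaphragm travel.  ``intensity_threshold`` zeroes the demons
    force where the image difference is below the noise floor — without it
    the force term (difference times gradient over a near-zero denominator)
    random-walks in flat regions and two identical noisy images come back
    with non-zero fields.
    """
    if presmooth:
        from scipy.ndimage import gaussian_filter
        fixed = gaussian_filter(np.asarray(fixed, dtype=float), presmooth)
        moving = gaussian_filter(np.asarray(moving, dtype=float), presmooth)
    f = _to_sitk(fixed, spacing)
    m = _to_sitk(moving, spacing)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(float(smoothing_sigma))
    demons.SetSmoothUpdateField(True)
    demons.SetUpdateFieldStandardDeviations(float(update_sigma))
    demons.SetIntensityDifferenceThreshold(float(intensity_threshold))

    field = None
    ndim = f.GetDimension()
    for shrink, n_iter in levels:
        fs = sitk.Shrink(f, [int(shrink)] * ndim) if shrink > 1 else f
        ms = sitk.Shrink(m, [int(shrink)] * ndim) if shrink > 1 else m
        demons.SetNumberOfIterations(int(n_iter))
        if field is None:
            field = demons.Execute(fs, ms)
        else:
            field = sitk.Cast(sitk.Resample(field, fs, sitk.Transform(),
                                            sitk.sitkLinear),
                              sitk.sitkVectorFloat64)
            field = demons.Execute(fs, ms, field)
    field = sitk.Cast(sitk.Resample(field, f, sitk.Transform(),
                                    sitk.sitkLinear), sitk.sitkVectorFloat64)
    arr = sitk.GetArrayFromImage(field)        # (nz, nx, 2) with (x, z) comps
    return np.stack([arr[..., 1], arr[..., 0]])   # (2, nz, nx), (z, x) mm


@dataclass
class RegistrationResult:
    """Per-image displacement fields to the per-position reference."""

    fields: np.ndarray         # (n_images, 2, nz, nx), pull-back mm
    residuals: np.ndarray      # post-warp mean abs diff / dynamic range
    outlier: np.ndarray        # bool per image
    reference_index: dict      # slice position -> image index of reference
    spacing_mm: tuple
    s_proxy: np.ndarray        # per-image surrogate (or trace proxy) used

    @property
    def n_images(self) -> int:
        return self.fields.shape[0]


def _residual(fixed, moving, field, spacing) -> float:
    warped = warp_array(moving, DisplacementField(field, spacing))
    rng = np.percentile(fixed, 98) - np.percentile(fixed, 2)
    return float(np.mean(np.abs(fixed - warped)) / max(rng, 1e-12))


def register_slices(mr: DynamicMRSeries, s_images: np.ndarray = None,
                    levels=DEFAULT_LEVELS, smoothing_sigma: float = 1.5,
                    intensity_threshold: float = 0.05,
                    outlier_factor: float = 5.0,
                    outlier_floor: float = 0.08) -> RegistrationResult:
    """Register every dynamic MR image to its slice position's reference.

    Parameters
    ----------
    s_images : ndarray, optional
        Aligned surrogate value per image (from the clock alignment).  When
        omitted, the diaphragm-edge trace serves as the proxy for choosing
        the end-exhale reference.
    outlier_factor, outlier_floor : float
        An image is flagged when its residual exceeds
        ``max(outlier_floor, outlier_factor * median residual)``.
    """
    from .surrogate import mr_diaphragm_trace

    if s_images is None:
        s_images = mr_diaphragm_trace(mr)
    s_images = np.asarray(s_images, dtype=float)
    if s_images.size != mr.n_images:
        raise ValueError("need one surrogate value per MR image")

    # end-exhale mode over all images
    hist, edges = np.histogram(s_images, bins=24)
    i = int(np.argmax(hist))
    s_mode = 0.5 * (edges[i] + edges[i + 1])

    shape = mr.images.shape[1:]
    fields = np.zeros((mr.n_images, 2) + shape)
    residuals = np.zeros(mr.n_images)
    reference_index = {}
    spacing = tuple(mr.spacing_mm)

    for p in np.unique(mr.slice_position):
        idx = np.where(mr.slice_position == p)[0]
        if idx.size < 2:
            raise ValueError(f"slice position {p} has fewer than 2 images")
        ref = idx[int(np.argmin(np.abs(s_images[idx] - s_mode)))]
        reference_index[int(p)] = int(ref)
        ref_img = mr.images[ref]
        for j in idx:
            if j == ref:
                continue  # reference maps to itself with the zero field
            fields[j] = register_pair(mr.images[j], ref_img, spacing,
                                      levels=levels,
                                      smoothing_sigma=smoothing_sigma,
                                      intensity_threshold=intensity_threshold)
            residuals[j] = _residual(mr.images[j], ref_img, fields[j],
                                     spacing)

    med = np.median(residuals[residuals > 0]) if np.any(residuals > 0) else 0.0
    thresh = max(outlier_floor, outlier_factor * med)
    outlier = residuals > thresh
    return RegistrationResult(fields=fields, residuals=residuals,
                              outlier=outlier,
                              reference_index=reference_index,
                              spacing_mm=spacing, s_proxy=s_images)
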