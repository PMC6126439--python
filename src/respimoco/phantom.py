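"""Digital breathing-thorax phantom.

The default geometry is a single coronal slab (axis 0: superior -> inferior,
axis 1: patient left -> right) holding a body outline, two lungs, a liver
whose dome forms the diaphragm boundary, and spherical (circular in 2D)
PET-avid lesions.  Activity is in kBq/mL, attenuation in 1/cm at 511 keV.

Ground-truth respiratory motion is generated in the same functional form the
motion model later fits — a per-voxel linear map from the surrogate amplitude
``s`` and its rate ``sdot`` to displacement — plus an optional quadratic
mismatch term for misspecification experiments.  The displacement amplitude
follows a smooth superior-inferior envelope peaking at the diaphragm, where
excursion defaults to the ~20 mm peak-to-peak typical of quiet breathing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DisplacementField, VoxelVolume

__all__ = ["Lesion", "PhantomSpec", "Phantom", "build_phantom",
           "GroundTruthMotion", "make_motion", "default_spec",
           "sphere_mask"]

# label-map codes
BG, SOFT, LUNG, LIVER = 0, 1, 2, 3

#: per-organ (activity kBq/mL, mu 1/cm, MR intensity a.u.)
DEFAULT_TISSUES = {
    "soft": (1.0, 0.096, 0.55),
    "lung": (0.3, 0.030, 0.10),
    "liver": (2.5, 0.096, 0.90),
}


@dataclass
class Lesion:
    """Spherical avid lesion: centre in world mm, diameter mm, kBq/mL."""
    center_mm: tuple
    diameter_mm: float = 10.0
    activity: float = 12.0

    def __post_init__(self):
        self.center_mm = tuple(float(c) for c in self.center_mm)
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be > 0")
        if self.activity < 0:
            raise ValueError("lesion activity must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry, tissue menu and SUV calibration of the phantom."""

    grid_shape: tuple = (128, 128)
    spacing_mm: tuple = (3.0, 3.0)
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    lesions: list = field(default_factory=list)
    weight_kg: float = 70.0
    dose_MBq: float = 350.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in np.atleast_1d(self.spacing_mm))
        if len(self.spacing_mm) == 1:
            self.spacing_mm = self.spacing_mm * len(self.grid_shape)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be > 0")
        for name, (act, mu, _) in self.tissues.items():
            if act < 0 or mu < 0:
                raise ValueError(f"tissue {name!r}: activity and mu must be >= 0")
        if self.weight_kg <= 0 or self.dose_MBq <= 0:
            raise ValueError("weight and dose must be > 0")

    @property
    def extent_mm(self):
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing_mm))


def sphere_mask(shape, spacing_mm, center_mm, diameter_mm) -> np.ndarray:
    """Boolean mask of voxel centres within diameter/2 of ``center_mm``."""
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing_mm)],
                         indexing="ij")
    r2 = sum((c - c0) ** 2 for c, c0 in zip(coords, center_mm))
    return r2 <= (diameter_mm / 2.0) ** 2


def _ellipse(shape, spacing, center_mm, semi_mm):
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    return sum(((c - c0) / a) ** 2
               for c, c0, a in zip(coords, center_mm, semi_mm)) <= 1.0


@dataclass
class Phantom:
    """Built phantom: co-registered activity, mu, labels and lesion masks."""

    spec: PhantomSpec
    activity: VoxelVolume
    mu: VoxelVolume
    labels: VoxelVolume
    mr_contrast: VoxelVolume
    lesion_masks: list
    body_mask: np.ndarray
    diaphragm_z_mm: float


def _scaled(frac, extent):
    return tuple(f * e for f, e in zip(frac, extent))


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a PhantomSpec into activity / mu / label volumes.

    2D coronal geometry: a body ellipse, two lungs, and a liver ellipse whose
    upper edge (inside the right lung) forms the diaphragm dome.  A trailing
    grid axis of length > 2 switches the same construction to 3D, extruding
    the coronal layout along the anterior-posterior axis.
    """
    shape, sp = spec.grid_shape, spec.spacing_mm
    extent = spec.extent_mm
    ndim = len(shape)
    if ndim not in (2, 3):
        raise ValueError("phantom grid must be 2D or 3D")

    # fractional landmark layout (of grid extent): z axis 0, x axis 1
    def frac(fz, fx):
        p = [fz * extent[0], fx * extent[1]]
        if ndim == 3:
            p.append(0.5 * extent[2])
        return tuple(p)

    def semi(fz, fx, fy=0.45):
        p = [fz * extent[0], fx * extent[1]]
        if ndim == 3:
            p.append(fy * extent[2])
        return tuple(p)

    body = _ellipse(shape, sp, frac(0.50, 0.50), semi(0.46, 0.40))
    lung_l = _ellipse(shape, sp, frac(0.28, 0.32), semi(0.20, 0.13, 0.30))
    lung_r = _ellipse(shape, sp, frac(0.28, 0.68), semi(0.20, 0.13, 0.30))
    liver = _ellipse(shape, sp, frac(0.57, 0.66), semi(0.16, 0.17, 0.32))

    labels = np.full(shape, BG, dtype=np.int16)
    labels[body] = SOFT
    labels[lung_l & body] = LUNG
    labels[lung_r & body] = LUNG
    labels[liver & body] = LIVER  # liver dome overwrites lung -> diaphragm

    act = np.zeros(shape)
    mu = np.zeros(shape)
    mr = np.zeros(shape)
    for code, name in ((SOFT, "soft"), (LUNG, "lung"), (LIVER, "liver")):
        a, m, c = spec.tissues[name]
        act[labels == code] = a
        mu[labels == code] = m
        mr[labels == code] = c

    lesion_masks = []
    for les in spec.lesions:
        mask = sphere_mask(shape, sp, les.center_mm, les.diameter_mm)
        if not mask.any():
            raise ValueError(f"lesion at {les.center_mm} rasterises to no voxels")
        if not body[mask].all():
            raise ValueError(f"lesion at {les.center_mm} extends outside the body")
        act[mask] = les.activity
        mr[mask] = 0.90
        lesion_masks.append(mask)

    # diaphragm: top edge of the liver region in the right-lung column band
    liver_mask = labels == LIVER
    if liver_mask.any():
        rows = np.where(liver_mask.any(axis=tuple(range(1, ndim))))[0]
        diaphragm_z = rows.min() * sp[0]
    else:
        diaphragm_z = 0.55 * extent[0]

    return Phantom(
        spec=spec,
        activity=VoxelVolume(act, sp, semantics="activity"),
        mu=VoxelVolume(mu, sp, semantics="mu"),
        labels=VoxelVolume(labels, sp, semantics="label"),
        mr_contrast=VoxelVolume(mr, sp, semantics="mr"),
        lesion_masks=lesion_masks,
        body_mask=body,
        diaphragm_z_mm=float(diaphragm_z),
    )


def default_spec(lesion_diameter_mm: float = 10.0,
                 lesion_activity: float = 12.0,
                 n_lesions: int = 1, seed: int = 0) -> PhantomSpec:
    """Default 128 x 128 (3 mm) thorax slab with liver-dome lesion(s).

    Lesion sites sit in the liver below the diaphragm dome — the region the
    clinical problem cares about most (lesions blurred/mislocated by the
    ~20 mm diaphragm excursion).
    """
    spec = PhantomSpec(seed=seed)
    ez, ex = spec.extent_mm[:2]
    sites = [(0.55, 0.66), (0.61, 0.58), (0.60, 0.74), (0.66, 0.68)]
    lesions = []
    for fz, fx in sites[:n_lesions]:
        center = [fz * ez, fx * ex]
        if len(spec.grid_shape) == 3:
            center.append(0.5 * spec.extent_mm[2])
        lesions.append(Lesion(tuple(center), lesion_diameter_mm, lesion_activity))
    spec.lesions = lesions
    return spec


class GroundTruthMotion:
    """Hidden-truth surrogate-to-displacement generator.

    Displacement at state (s, sdot) is ``g0 + g1*s + g2*sdot`` per voxel
    (pull-back, mm) plus ``q*s^2`` along the superior-inferior axis when the
    mismatch mode is enabled.  ``g0`` is identically zero so (s=0, sdot=0)
    is the reference (identity) state.
    """

    def __init__(self, grid_shape, spacing_mm, diaphragm_z_mm,
                 excursion_mm: float = 20.0, envelope_sigma_mm: float = 70.0,
                 hysteresis_mm_s: float = 2.0, lateral_fraction: float = 0.1,
                 mismatch_mm: float = 0.0):
        self.grid_shape = tuple(grid_shape)
        self.spacing = tuple(float(s) for s in np.atleast_1d(spacing_mm))
        if len(self.spacing) == 1:
            self.spacing = self.spacing * len(self.grid_shape)
        self.diaphragm_z_mm = float(diaphragm_z_mm)
        self.excursion_mm = float(excursion_mm)
        self.envelope_sigma_mm = float(envelope_sigma_mm)
        self.hysteresis_mm_s = float(hysteresis_mm_s)
        self.lateral_fraction = float(lateral_fraction)
        self.mismatch_mm = float(mismatch_mm)

        ndim = len(self.grid_shape)
        z = np.arange(self.grid_shape[0]) * self.spacing[0]
        x = np.arange(self.grid_shape[1]) * self.spacing[1]
        w_z = np.exp(-0.5 * ((z - self.diaphragm_z_mm)
                             / self.envelope_sigma_mm) ** 2)
        shape_bcast = [1] * ndim
        shape_bcast[0] = -1
        self._w = np.broadcast_to(w_z.reshape(shape_bcast),
                                  self.grid_shape).copy()
        # lateral expansion: outward from the midline, scaled by the envelope
        x_c = x - x.mean()
        lat = np.tanh(x_c / (0.25 * np.ptp(x) + 1e-12))
        shape_bx = [1] * ndim
        shape_bx[1] = -1
        self._lat = self._w * np.broadcast_to(lat.reshape(shape_bx),
                                              self.grid_shape)

        # per-voxel linear generator coefficients (pull-back mm)
        self.g1 = np.zeros((ndim,) + self.grid_shape)
        self.g1[0] = -self.excursion_mm * self._w       # inferior shift at inhale
        self.g1[1] = -self.excursion_mm * self.lateral_fraction * self._lat
        self.g2 = np.zeros_like(self.g1)
        self.g2[0] = -self.hysteresis_mm_s * self._w
        self.g0 = np.zeros_like(self.g1)

    def amplitude_at(self, point_mm) -> float:
        """Envelope factor (0..1) at a world point; lesion displacement
        amplitude is ``excursion_mm * amplitude_at(lesion centre)``."""
        z = float(point_mm[0])
        return float(np.exp(-0.5 * ((z - self.diaphragm_z_mm)
                                    / self.envelope_sigma_mm) ** 2))

    def motion_at(self, s: float, sdot: float = 0.0) -> DisplacementField:
        """Evaluate the generator at a surrogate state (pull-back field, mm)."""
        if not (np.isfinite(s) and np.isfinite(sdot)):
            raise ValueError("surrogate state must be finite")
        data = self.g0 + self.g1 * float(s) + self.g2 * float(sdot)
        if self.mismatch_mm:
            data = data.copy()
            data[0] += -self.mismatch_mm * self._w * float(s) ** 2
        return DisplacementField(data, self.spacing)

    @property
    def max_displacement_mm(self) -> float:
        """Stated bound on |displacement| at |s| <= 1.3, |sdot| <= 1.5."""
        return (1.3 * (1 + self.lateral_fraction) * self.excursion_mm
                + 1.5 * self.hysteresis_mm_s + 1.69 * abs(self.mismatch_mm))


def make_motion(phantom: Phantom, excursion_mm: float = 20.0,
                hysteresis_mm_s: float = 2.0,
                mismatch_mm: float = 0.0, **kw) -> GroundTruthMotion:
    """Ground-truth motion matched to a built phantom's grid and diaphragm."""
    return GroundTruthMotion(phantom.spec.grid_shape, phantom.spec.spacing_mm,
                             phantom.diaphragm_z_mm, excursion_mm=excursion_mm,
                             hysteresis_mm_s=hysteresis_mm_s,
                             mismatch_mm=mismatch_mm, **kw)
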