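"""Regular-grid scalar volumes and displacement fields.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinate = origin + index * spacing (mm);
* in 2D coronal mode axis 0 runs superior -> inferior and axis 1 left -> right;
* displacement fields are *pull-back* (resampling) fields in mm: the warped
  image is ``out[x] = in[x + d(x)/spacing]``.  Forward (push) fields are never
  exposed; where an inverse is needed it is computed by fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["VoxelVolume", "DisplacementField", "warp", "invert_field"]

#: recognised intensity-semantics tags
SEMANTICS = ("activity", "mu", "mr", "suv", "label", "generic")


@dataclass
class VoxelVolume:
    """Scalar field on a regular grid.

    Parameters
    ----------
    values : ndarray
        Voxel values, any dimensionality.
    spacing : tuple of float
        Voxel spacing in mm, one entry per axis, all > 0.
    origin : tuple of float
        World coordinate (mm) of voxel (0, ..., 0).
    semantics : str
        Intensity meaning: ``activity`` (kBq/mL), ``mu`` (1/cm at 511 keV),
        ``mr`` (a.u.), ``suv`` (dimensionless), ``label`` or ``generic``.
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple = None
    semantics: str = "generic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float) if self.semantics != "label" else np.asarray(self.values)
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(self.spacing) == 1:
            self.spacing = self.spacing * self.values.ndim
        if self.origin is None:
            self.origin = (0.0,) * self.values.ndim
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != self.values.ndim:
            raise ValueError("spacing must have one entry per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be > 0")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics tag {self.semantics!r}")
        if not np.all(np.isfinite(np.asarray(self.values, dtype=float))):
            raise ValueError("volume values must be finite")

    @property
    def shape(self):
        return self.values.shape

    @property
    def ndim(self):
        return self.values.ndim

    def with_values(self, values, semantics=None) -> "VoxelVolume":
        return VoxelVolume(np.asarray(values), self.spacing, self.origin,
                           semantics or self.semantics)

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def world_coords(self):
        """Per-axis world coordinates (mm) of voxel centres."""
        return [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
                for a in range(self.ndim)]


@dataclass
class DisplacementField:
    """Per-voxel pull-back displacement vectors in mm.

    ``data`` has shape ``(ndim, *grid)``; component ``a`` displaces along
    array axis ``a``.  A zero field warps to the identity to machine
    precision.
    """

    data: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(self.spacing) == 1:
            self.spacing = self.spacing * (self.data.ndim - 1)
        if self.data.shape[0] != self.data.ndim - 1:
            raise ValueError("field data must have shape (ndim, *grid)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field must be finite")

    @property
    def grid_shape(self):
        return self.data.shape[1:]

    @property
    def ndim(self):
        return self.data.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.data ** 2).sum(axis=0))

    def __add__(self, other: "DisplacementField") -> "DisplacementField":
        return DisplacementField(self.data + other.data, self.spacing)

    def __mul__(self, scalar: float) -> "DisplacementField":
        return DisplacementField(self.data * scalar, self.spacing)

    __rmul__ = __mul__

    @classmethod
    def zero(cls, shape, spacing) -> "DisplacementField":
        return cls(np.zeros((len(shape),) + tuple(shape)), spacing)


def _sample_coords(fld: DisplacementField) -> np.ndarray:
    """Voxel-index sampling coordinates implied by a pull-back field."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in fld.grid_shape],
                        indexing="ij")
    sp = np.asarray(fld.spacing).reshape((-1,) + (1,) * len(fld.grid_shape))
    return np.stack(grids) + fld.data / sp


def warp(volume: VoxelVolume, fld: DisplacementField, order: int = 1,
         fill: float | None = None) -> VoxelVolume:
    """Pull-back resampling of `volume` through `fld`.

    Out-of-grid samples take ``fill`` (default 0, the natural fill for both
    activity and attenuation).  ``order=1`` (linear) by default; a zero field
    returns the input values exactly.
    """
    if volume.shape != fld.grid_shape:
        raise ValueError("volume and field must share a grid")
    if not np.allclose(volume.spacing, fld.spacing):
        raise ValueError("volume and field must share voxel spacing")
    if fill is None:
        fill = 0.0
    if not np.any(fld.data):
        return volume.with_values(volume.values.copy())
    coords = _sample_coords(fld)
    out = ndimage.map_coordinates(volume.values, coords, order=order,
                                  mode="grid-constant", cval=fill)
    return volume.with_values(out)


def warp_array(values: np.ndarray, fld: DisplacementField, order: int = 1,
               fill: float = 0.0) -> np.ndarray:
    """`warp` on a bare array sharing the field's grid."""
    if values.shape != fld.grid_shape:
        raise ValueError("array and field must share a grid")
    if not np.any(fld.data):
        return values.copy()
    coords = _sample_coords(fld)
    return ndimage.map_coordinates(values, coords, order=order,
                                   mode="grid-constant", cval=fill)


def invert_field(fld: DisplacementField, n_iter: int = 30,
                 tol: float = 1e-3) -> DisplacementField:
    """Approximate inverse of a pull-back field by fixed-point iteration.

    Solves ``e(x) = -d(x + e(x))`` so that warping with ``e`` undoes warping
    with ``d`` (up to interpolation error).  Converges for the smooth,
    moderate-amplitude respiratory fields used here.
    """
    inv = np.zeros_like(fld.data)
    sp = np.asarray(fld.spacing).reshape((-1,) + (1,) * len(fld.grid_shape))
    for _ in range(n_iter):
        coords = np.stack(np.meshgrid(
            *[np.arange(n, dtype=float) for n in fld.grid_shape],
            indexing="ij")) + inv / sp
        sampled = np.stack([
            ndimage.map_coordinates(fld.data[a], coords, order=1,
                                    mode="nearest")
            for a in range(fld.ndim)])
        new = -sampled
        delta = np.abs(new - inv).max()
        inv = new
        if delta < tol:
            break
    return DisplacementField(inv, fld.spacing)
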