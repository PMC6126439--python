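"""Parallel-beam 2D projector with an exactly matched adjoint.

Iterative emission reconstruction (OSEM / MCIR) needs forward and
back-projection operators that are true adjoints of each other, otherwise the
multiplicative EM update loses its convergence behaviour.  The projector here
represents image rotation as an explicit sparse bilinear-resampling matrix
``R_theta``; the forward projection at angle theta is a column sum of the
rotated image times the ray step, and the back-projection is the transpose of
that composition — adjoint by construction, to machine precision.

Attenuation enters as per-line factors ``exp(-integral mu dl)`` computed with
the same line integrals, so an attenuated projection stays a linear operator
``diag(a) . P`` whose adjoint is ``P^T . diag(a)``.

The same sparse-resampling machinery builds warp matrices from displacement
fields, giving the motion-compensated system model its adjoint warps too.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .grids import DisplacementField

__all__ = ["Projector", "resample_matrix", "warp_matrix"]

MM_TO_CM = 0.1


def resample_matrix(shape, sample_coords) -> sparse.csr_matrix:
    """Sparse matrix S with (S x)[i] = bilinear sample of image x at
    ``sample_coords[:, i]`` (voxel-index units); out-of-grid weight is
    dropped (zero fill)."""
    ndim = len(shape)
    npts = sample_coords.shape[1]
    base = np.floor(sample_coords).astype(np.int64)
    frac = sample_coords - base

    rows, cols, vals = [], [], []
    for corner in range(2 ** ndim):
        offs = [(corner >> a) & 1 for a in range(ndim)]
        idx = base + np.array(offs)[:, None]
        w = np.ones(npts)
        inside = np.ones(npts, dtype=bool)
        for a in range(ndim):
            w = w * (frac[a] if offs[a] else 1.0 - frac[a])
            inside &= (idx[a] >= 0) & (idx[a] < shape[a])
        keep = inside & (w > 0)
        flat = np.zeros(npts, dtype=np.int64)
        mult = 1
        for a in range(ndim - 1, -1, -1):
            flat += idx[a].clip(0, shape[a] - 1) * mult
            mult *= shape[a]
        rows.append(np.nonzero(keep)[0])
        cols.append(flat[keep])
        vals.append(w[keep])
    n = int(np.prod(shape))
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(npts, n))


def warp_matrix(field: DisplacementField) -> sparse.csr_matrix:
    """Sparse pull-back warp operator equivalent to ``grids.warp`` (order 1)."""
    shape = field.grid_shape
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    sp = np.asarray(field.spacing).reshape((-1,) + (1,) * len(shape))
    coords = (np.stack(grids) + field.data / sp).reshape(len(shape), -1)
    return resample_matrix(shape, coords)


class Projector:
    """Ideal parallel-beam projector on a square 2D grid.

    Parameters
    ----------
    shape : (nz, nx)
        Image grid; radial bins equal ``max(shape)``.
    spacing_mm : float or pair
        Voxel spacing; also the ray step along each line.
    n_angles : int
        Projection angles uniformly covering [0, pi).
    psf_fwhm_mm : float
        Optional in-plane detector-resolution blur applied to the sinogram
        radial axis (0 = ideal detector; 4.5 mm emulates a clinical system).
    """

    def __init__(self, shape, spacing_mm=3.0, n_angles: int = 126,
                 psf_fwhm_mm: float = 0.0):
        if len(shape) != 2:
            raise ValueError("projector supports 2D grids")
        self.shape = tuple(int(n) for n in shape)
        sp = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
        if sp.size == 1:
            sp = np.repeat(sp, 2)
        if not np.allclose(sp[0], sp[1]):
            raise ValueError("projector requires isotropic in-plane spacing")
        self.spacing = float(sp[0])
        self.n_angles = int(n_angles)
        self.angles = np.arange(self.n_angles) * np.pi / self.n_angles
        self.n_rad = max(self.shape)
        self.psf_fwhm_mm = float(psf_fwhm_mm)
        self._rot = [self._rotation_matrix(th) for th in self.angles]
        self._rot_T = [R.T.tocsr() for R in self._rot]

    # -- geometry -----------------------------------------------------------
    def _rotation_matrix(self, theta: float) -> sparse.csr_matrix:
        """Resampler from the image grid onto a grid rotated by ``theta``.

        The rotated grid is (n_ray, n_rad): axis 0 runs along the ray
        (summed), axis 1 is the radial detector coordinate.
        """
        n_ray = self.n_rad
        cz = (self.shape[0] - 1) / 2.0
        cx = (self.shape[1] - 1) / 2.0
        cu = (n_ray - 1) / 2.0
        cr = (self.n_rad - 1) / 2.0
        u, r = np.meshgrid(np.arange(n_ray, dtype=float),
                           np.arange(self.n_rad, dtype=float), indexing="ij")
        du, dr = u - cu, r - cr
        ct, st = np.cos(theta), np.sin(theta)
        z = cz + du * ct - dr * st
        x = cx + du * st + dr * ct
        coords = np.stack([z.ravel(), x.ravel()])
        return resample_matrix(self.shape, coords)

    def _psf(self, sino: np.ndarray) -> np.ndarray:
        if self.psf_fwhm_mm <= 0:
            return sino
        from scipy.ndimage import gaussian_filter1d
        sigma = self.psf_fwhm_mm / 2.35482 / self.spacing
        return gaussian_filter1d(sino, sigma, axis=-1, mode="constant")

    # -- operators ----------------------------------------------------------
    def forward(self, image: np.ndarray, angle_idx=None) -> np.ndarray:
        """Line integrals (value * mm) of ``image``, shape (n_angles, n_rad)."""
        if image.shape != self.shape:
            raise ValueError("image does not match projector grid")
        idx = list(range(self.n_angles)) if angle_idx is None else list(angle_idx)
        x = image.ravel()
        out = np.empty((len(idx), self.n_rad))
        for row, i in enumerate(idx):
            rot = (self._rot[i] @ x).reshape(self.n_rad, self.n_rad)
            out[row] = rot.sum(axis=0) * self.spacing
        return self._psf(out)

    def back(self, sino: np.ndarray, angle_idx=None) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        idx = list(range(self.n_angles)) if angle_idx is None else list(angle_idx)
        sino = self._psf(np.asarray(sino, dtype=float))
        out = np.zeros(int(np.prod(self.shape)))
        for row, i in enumerate(idx):
            tiled = np.broadcast_to(sino[row] * self.spacing,
                                    (self.n_rad, self.n_rad)).ravel()
            out += self._rot_T[i] @ tiled
        return out.reshape(self.shape)

    def forward_many(self, images: np.ndarray) -> np.ndarray:
        """Unblurred line integrals of a stack of images in one pass per
        angle (shared sparse products; used by the frame simulator)."""
        k = images.shape[0]
        X = images.reshape(k, -1).T  # (npix, k)
        out = np.empty((k, self.n_angles, self.n_rad))
        for i in range(self.n_angles):
            rot = (self._rot[i] @ X).reshape(self.n_rad, self.n_rad, k)
            out[:, i, :] = rot.sum(axis=0).T * self.spacing
        return out

    def attenuation_factors(self, mu: np.ndarray, angle_idx=None) -> np.ndarray:
        """Per-line survival factors exp(-integral mu dl), mu in 1/cm."""
        if np.any(mu < 0):
            raise ValueError("mu must be >= 0")
        lines = self.forward_unblurred(mu, angle_idx)  # (1/cm)*mm
        return np.exp(-MM_TO_CM * lines)

    def forward_unblurred(self, image, angle_idx=None):
        psf = self.psf_fwhm_mm
        self.psf_fwhm_mm = 0.0
        try:
            return self.forward(image, angle_idx)
        finally:
            self.psf_fwhm_mm = psf


_PROJECTOR_CACHE: dict = {}


def get_projector(shape, spacing_mm, n_angles, psf_fwhm_mm=0.0) -> Projector:
    """Memoised projector factory (matrices are expensive to rebuild)."""
    key = (tuple(shape), float(np.atleast_1d(spacing_mm)[0]), int(n_angles),
           float(psf_fwhm_mm))
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = Projector(shape, spacing_mm, n_angles,
                                          psf_fwhm_mm)
    return _PROJECTOR_CACHE[key]
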