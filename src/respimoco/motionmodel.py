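"""Per-voxel surrogate-driven linear motion model.

The model links the respiratory surrogate amplitude ``s`` and its time
derivative ``sdot`` to the tissue displacement at every voxel:

    d(x; s, sdot) = c0(x) + c1(x) * s + c2(x) * sdot        [mm, pull-back]

The two-surrogate form captures hysteresis — at equal amplitude, tissue sits
at different positions during inspiration (sdot > 0) and expiration
(sdot < 0) — which a single-surrogate model cannot represent.  Because the
model is continuous in (s, sdot) it interpolates *and extrapolates* to any
respiratory state, so every PET event can be corrected and deformations can
be estimated even at states never visited during the model-building minute
(e.g. the deep-inhale breath-hold of the attenuation-map acquisition).

Fitting is per voxel and per displacement component, by iteratively
reweighted least squares with Huber weights, making the model robust to the
occasional failed slice registration.

The module follows the Model/Results idiom: :class:`MotionModel` is built
from data and ``fit()`` returns a :class:`MotionModelResult` carrying the
coefficient maps, diagnostics, ``predict_field`` and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .grids import DisplacementField

__all__ = ["MotionModel", "MotionModelResult", "interpolate_through_plane"]

HUBER_C = 1.345  # 95% Gaussian efficiency tuning constant


class DegenerateSurrogateError(ValueError):
    """Raised when the fit design is rank-deficient (constant or collinear
    surrogate)."""


def _huber_irls(X: np.ndarray, Y: np.ndarray, n_iter: int = 8,
                tol: float = 1e-8):
    """Vectorised Huber IRLS: solve ``Y ~ X beta`` independently per column.

    X is (n_obs, p); Y is (n_obs, m).  Returns (beta (p, m), weights
    (n_obs, m)).
    """
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ Y)
    w = np.ones_like(Y)
    for _ in range(n_iter):
        R = Y - X @ beta
        mad = np.median(np.abs(R - np.median(R, axis=0)), axis=0)
        sigma = np.maximum(1.4826 * mad, 1e-9)
        a = np.abs(R) / sigma
        w = np.minimum(1.0, HUBER_C / np.maximum(a, 1e-12))
        A = np.einsum("oi,om,oj->mij", X, w, X)
        b = np.einsum("oi,om->mi", X, w * Y)
        new = np.linalg.solve(A, b[..., None])[..., 0].T  # (p, m)
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta, w


@dataclass
class MotionModel:
    """Unfitted model: registered displacement data + surrogate pairs.

    Parameters
    ----------
    fields : ndarray, (n_obs, ndim, \\*grid)
        Per-image pull-back displacement fields (mm) to the reference.
    s, sdot : ndarray, (n_obs,)
        Surrogate amplitude and gradient at each image's acquisition time,
        already mapped to the PET clock.
    spacing_mm : tuple
        Grid spacing of the fields.
    exclude : ndarray of bool, optional
        Observations to drop (e.g. registration outliers).
    """

    fields: np.ndarray
    s: np.ndarray
    sdot: np.ndarray
    spacing_mm: tuple
    exclude: np.ndarray = None

    @classmethod
    def from_registration(cls, reg, surr, alignment, mr) -> "MotionModel":
        """Assemble the model data from the pipeline stages.

        Maps every MR timestamp to the PET clock through the alignment,
        interpolates the surrogate pair there, and carries the registration
        outlier flags through as exclusions.
        """
        t_pet = alignment.to_pet_time(mr.t_mr)
        s = np.interp(t_pet, surr.t, surr.s)
        sdot = np.interp(t_pet, surr.t, surr.sdot)
        return cls(fields=reg.fields, s=s, sdot=sdot,
                   spacing_mm=reg.spacing_mm, exclude=reg.outlier.copy())

    def fit(self, robust: str = "huber", surrogates=("s", "sdot"),
            min_obs: int = 6) -> "MotionModelResult":
        """Fit the per-voxel linear model.

        ``robust='huber'`` (default) runs Huber IRLS; ``'ols'`` plain least
        squares.  ``surrogates=('s',)`` fits the amplitude-only comparison
        model.
        """
        use = np.ones(len(self.s), dtype=bool)
        if self.exclude is not None:
            use &= ~np.asarray(self.exclude, dtype=bool)
        if use.sum() < max(min_obs, len(surrogates) + 1):
            raise ValueError("too few usable images to fit the model")

        s = np.asarray(self.s, dtype=float)[use]
        sdot = np.asarray(self.sdot, dtype=float)[use]
        cols = [np.ones_like(s)]
        names = ["const"]
        if "s" in surrogates:
            if s.std() < 1e-12:
                raise DegenerateSurrogateError("surrogate s is constant")
            cols.append(s)
            names.append("s")
        if "sdot" in surrogates:
            if sdot.std() < 1e-12:
                raise DegenerateSurrogateError("surrogate sdot is constant")
            cols.append(sdot)
            names.append("sdot")
        X = np.stack(cols, axis=1)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateSurrogateError("surrogates are collinear")

        Y = self.fields[use].reshape(use.sum(), -1)
        if robust == "huber":
            beta, w = _huber_irls(X, Y)
        elif robust == "ols":
            beta = np.linalg.solve(X.T @ X, X.T @ Y)
            w = np.ones_like(Y)
        else:
            raise ValueError(f"unknown robustness scheme {robust!r}")

        fitted = X @ beta
        ss_res = ((Y - fitted) ** 2).sum(axis=0)
        ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.maximum(ss_tot, 1e-30), 0.0)

        grid_shape = self.fields.shape[2:]
        ndim = self.fields.shape[1]
        coef = beta.reshape(X.shape[1], ndim, *grid_shape)
        # fit-reference state: modal end-exhale amplitude, zero gradient
        hist, edges = np.histogram(s, bins=24)
        i = int(np.argmax(hist))
        ref_state = (float(0.5 * (edges[i] + edges[i + 1])), 0.0)

        return MotionModelResult(
            coef=coef, term_names=tuple(names), spacing_mm=self.spacing_mm,
            r_squared=r2.reshape(ndim, *grid_shape),
            weight_sum=w.sum(axis=0).reshape(ndim, *grid_shape),
            n_obs=int(use.sum()), n_excluded=int((~use).sum()),
            s_range=(float(s.min()), float(s.max())),
            sdot_range=(float(sdot.min()), float(sdot.max())),
            ref_state=ref_state, robust=robust)


@dataclass
class MotionModelResult:
    """Fitted motion model: coefficient maps, diagnostics, prediction."""

    coef: np.ndarray           # (n_terms, ndim, *grid), mm per unit regressor
    term_names: tuple
    spacing_mm: tuple
    r_squared: np.ndarray
    weight_sum: np.ndarray
    n_obs: int
    n_excluded: int
    s_range: tuple
    sdot_range: tuple
    ref_state: tuple
    robust: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("fitted coefficients must be finite")

    @classmethod
    def zero(cls, grid_shape, spacing_mm, ndim: int = None
             ) -> "MotionModelResult":
        """Null model (all coefficients zero): predicts the identity warp at
        every state.  Used when no respiratory signal is detectable — the
        correct correction is then no correction."""
        ndim = ndim if ndim is not None else len(grid_shape)
        coef = np.zeros((3, ndim) + tuple(grid_shape))
        return cls(coef=coef, term_names=("const", "s", "sdot"),
                   spacing_mm=tuple(spacing_mm),
                   r_squared=np.zeros((ndim,) + tuple(grid_shape)),
                   weight_sum=np.zeros((ndim,) + tuple(grid_shape)),
                   n_obs=0, n_excluded=0, s_range=(0.0, 0.0),
                   sdot_range=(0.0, 0.0), ref_state=(0.0, 0.0),
                   robust="null")

    @property
    def grid_shape(self):
        return self.coef.shape[2:]

    def _term(self, name):
        if name not in self.term_names:
            return 0.0
        return self.coef[self.term_names.index(name)]

    @property
    def c0(self):
        return self._term("const")

    @property
    def c1(self):
        return self._term("s")

    @property
    def c2(self):
        return self._term("sdot")

    def predict_field(self, s: float, sdot: float = 0.0) -> DisplacementField:
        """Displacement field at an arbitrary surrogate state (mm).

        States outside the fitted range are permitted — that is the
        extrapolation the continuous model exists for — and are flagged in
        the returned field's ``meta``.
        """
        if not (np.isfinite(s) and np.isfinite(sdot)):
            raise ValueError("surrogate state must be finite")
        data = (np.asarray(self.c0)
                + np.asarray(self.c1) * float(s)
                + np.asarray(self.c2) * float(sdot))
        if np.isscalar(data) or data.shape == ():
            raise ValueError("model has no spatial terms")
        fld = DisplacementField(np.array(data, dtype=float), self.spacing_mm)
        extrapolated = not (self.s_range[0] <= s <= self.s_range[1]
                            and self.sdot_range[0] <= sdot <= self.sdot_range[1])
        fld.meta = {"s": float(s), "sdot": float(sdot),
                    "extrapolated": bool(extrapolated)}
        return fld

    def mean_abs(self, term: str) -> float:
        return float(np.mean(np.abs(self._term(term))))

    def summary(self) -> str:
        lines = [
            "Surrogate-driven linear motion model",
            "=" * 44,
            f"terms          : {' + '.join(self.term_names)}",
            f"robust scheme  : {self.robust}",
            f"images used    : {self.n_obs} (excluded: {self.n_excluded})",
            f"s fit range    : [{self.s_range[0]:.3f}, {self.s_range[1]:.3f}]",
            f"sdot fit range : [{self.sdot_range[0]:.3f}, {self.sdot_range[1]:.3f}] /s",
            f"reference state: s={self.ref_state[0]:.3f}, sdot={self.ref_state[1]:.1f}",
            f"median R^2     : {float(np.median(self.r_squared)):.4f}",
        ]
        for name in self.term_names:
            c = self._term(name)
            lines.append(f"|{name:<5}| mm    : mean {np.abs(c).mean():8.4f}"
                         f"  max {np.abs(c).max():8.4f}")
        return "\n".join(lines)


def interpolate_through_plane(coef_planes: np.ndarray,
                              plane_positions_mm: np.ndarray,
                              target_positions_mm: np.ndarray) -> np.ndarray:
    """Cubic interpolation of coefficient maps across slice positions.

    For 3D use: the dynamic MR samples a sparse set of sagittal planes
    (25-mm centres clinically); coefficients at intermediate planes are
    filled by a cubic spline along the slice normal, justified by the
    smoothness of respiratory deformation.

    ``coef_planes`` has the plane axis first; returns the same layout at
    ``target_positions_mm``.
    """
    pos = np.asarray(plane_positions_mm, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least 2 planes to interpolate")
    spl = CubicSpline(pos, coef_planes, axis=0,
                      bc_type="natural", extrapolate=True)
    return spl(np.asarray(target_positions_mm, dtype=float))
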