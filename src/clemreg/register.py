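"""Probabilistic point-set registration by coherent point drift (CPD).

The moving (source) cloud is treated as the centroids of an isotropic
Gaussian mixture, the fixed (target) cloud as data drawn from it, plus a
uniform outlier component with weight ``w``.  Expectation-maximization
alternates soft correspondences (E-step) with a closed-form transform and
variance update (M-step).  Three transform families are provided:

* rigid/similarity — rotation via SVD of the weighted cross-covariance,
  optional global scale, translation;
* affine — closed-form linear solve;
* nonrigid — a coherent Gaussian-kernel displacement field on the source
  points with motion-coherence regularization ``lam`` and bandwidth ``beta``.

Estimators follow the scikit-learn protocol: parameters in ``__init__``,
``fit(source, target)``, fitted attributes with trailing underscores, and
``transform(points)`` applying the recovered mapping.  The module-level
functions ``rigid_cpd`` / ``affine_cpd`` / ``nonrigid_register`` are thin
wrappers returning a :class:`RegistrationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .transforms import AffineTransform, RigidTransform, SpatialTransform
from .volio import PointCloud

__all__ = [
    "RigidCPD",
    "AffineCPD",
    "NonrigidCPD",
    "RegistrationResult",
    "rigid_cpd",
    "affine_cpd",
    "nonrigid_register",
    "apply_transform",
]

_SIGMA2_FLOOR = 1e-12


@dataclass
class RegistrationResult:
    """Outcome of a CPD run: the transform plus convergence diagnostics."""

    transform: SpatialTransform
    iterations: int
    sigma2_trace: List[float]
    objective_trace: List[float]
    converged: bool
    w: float

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma2_trace):
            raise ValueError("sigma2 trace must be positive")


def _as_points(pc) -> np.ndarray:
    if isinstance(pc, PointCloud):
        return np.asarray(pc.points, dtype=float)
    return np.atleast_2d(np.asarray(pc, dtype=float))


def _validate_clouds(x: np.ndarray, y: np.ndarray) -> None:
    for name, arr in (("target", x), ("source", y)):
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"{name} cloud must be Nx3")
        if arr.shape[0] < 3:
            raise ValueError(f"{name} cloud needs at least 3 points")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} cloud contains non-finite coordinates")
    for name, arr in (("target", x), ("source", y)):
        centred = arr - arr.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
            raise ValueError(f"{name} cloud is degenerate (collinear points)")


def _initial_sigma2(x: np.ndarray, y: np.ndarray) -> float:
    n, d = x.shape
    m = y.shape[0]
    diff = (x ** 2).sum() * m + (y ** 2).sum() * n - 2.0 * (x.sum(0) @ y.sum(0))
    return max(diff / (d * n * m), _SIGMA2_FLOOR)


def _e_step(x: np.ndarray, ty: np.ndarray, sigma2: float, w: float):
    """Soft correspondences P (M x N) and the negative log-likelihood.

    Returns (P, nll).  The NLL includes all sigma2-dependent terms so the EM
    monotonicity guarantee applies to the recorded trace.
    """
    n, d = x.shape
    m = ty.shape[0]
    diff2 = ((x[None, :, :] - ty[:, None, :]) ** 2).sum(axis=2)
    p = np.exp(-diff2 / (2.0 * sigma2))
    c = (2.0 * np.pi * sigma2) ** (d / 2.0) * w / max(1.0 - w, 1e-12) * m / n
    den = p.sum(axis=0) + c
    den = np.maximum(den, 1e-300)
    nll = float(-np.log(den).sum()
                + n * d / 2.0 * np.log(2.0 * np.pi * sigma2)
                + n * np.log(m))
    p /= den[None, :]
    return p, nll


class _BaseCPD(BaseEstimator):
    """Shared EM loop; subclasses implement the M-step and transform."""

    #: rigid/affine pre-center the clouds for conditioning and recompose the
    #: translation; the nonrigid field is fitted in original coordinates so
    #: that the stiffness limit lam -> inf recovers zero displacement
    _centers_clouds = True

    def __init__(self, max_iter: int = 50, w: float = 0.0, tol: float = 1e-6):
        self.max_iter = max_iter
        self.w = w
        self.tol = tol

    # subclass hooks -----------------------------------------------------
    def _init_state(self, x: np.ndarray, y: np.ndarray) -> None:
        raise NotImplementedError

    def _m_step(self, x: np.ndarray, y: np.ndarray, p: np.ndarray) -> float:
        """Update transform parameters; return the new sigma2."""
        raise NotImplementedError

    def _transform_centered(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _finalize(self, mu_x: np.ndarray, mu_y: np.ndarray) -> None:
        raise NotImplementedError

    # EM loop ------------------------------------------------------------
    def fit(self, source, target):
        """Fit the transform mapping ``source`` onto ``target``."""
        y = _as_points(source)
        x = _as_points(target)
        _validate_clouds(x, y)
        if not (0.0 <= self.w < 1.0):
            raise ValueError("outlier weight w must be in [0, 1)")
        # center both clouds for conditioning; recompose translation at the end
        if self._centers_clouds:
            mu_x = x.mean(axis=0)
            mu_y = y.mean(axis=0)
        else:
            mu_x = np.zeros(3)
            mu_y = np.zeros(3)
        xc = x - mu_x
        yc = y - mu_y

        self._init_state(xc, yc)
        sigma2 = _initial_sigma2(xc, yc)
        self.sigma2_trace_ = []
        self.objective_trace_ = []
        self.converged_ = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            ty = self._transform_centered(yc)
            p, nll = _e_step(xc, ty, sigma2, self.w)
            new_sigma2 = self._m_step(xc, yc, p)
            new_sigma2 = max(new_sigma2, _SIGMA2_FLOOR)
            self.objective_trace_.append(nll)
            self.sigma2_trace_.append(new_sigma2)
            if abs(sigma2 - new_sigma2) < self.tol:
                sigma2 = new_sigma2
                self.converged_ = True
                break
            sigma2 = new_sigma2
        self.n_iter_ = n_iter
        self.sigma2_ = sigma2
        self._finalize(mu_x, mu_y)
        return self

    def fit_result(self, source, target) -> RegistrationResult:
        self.fit(source, target)
        return RegistrationResult(
            transform=self.transform_,
            iterations=self.n_iter_,
            sigma2_trace=list(self.sigma2_trace_),
            objective_trace=list(self.objective_trace_),
            converged=self.converged_,
            w=self.w,
        )

    def transform(self, points):
        pts = _as_points(points)
        return self.transform_.apply(pts)


class RigidCPD(_BaseCPD):
    """Rigid (similarity) coherent point drift.

    Fitted attributes: ``rotation_`` (3x3), ``translation_`` (3,), ``scale_``,
    ``sigma2_``, ``sigma2_trace_``, ``objective_trace_``, ``n_iter_``,
    ``converged_``, ``transform_``.
    """

    def __init__(self, max_iter: int = 50, w: float = 0.0, tol: float = 1e-6,
                 estimate_scale: bool = True):
        super().__init__(max_iter=max_iter, w=w, tol=tol)
        self.estimate_scale = estimate_scale

    def _init_state(self, x, y):
        self._r = np.eye(3)
        self._s = 1.0
        self._t = np.zeros(3)

    def _transform_centered(self, y):
        return self._s * y @ self._r.T + self._t

    def _m_step(self, x, y, p):
        n_p = p.sum()
        p1 = p.sum(axis=1)          # (M,)
        pt1 = p.sum(axis=0)         # (N,)
        mu_x = (pt1 @ x) / n_p
        mu_y = (p1 @ y) / n_p
        xh = x - mu_x
        yh = y - mu_y
        a = xh.T @ p.T @ yh         # D x D weighted cross-covariance
        u, s_vals, vt = np.linalg.svd(a)
        c = np.ones(3)
        c[-1] = np.sign(np.linalg.det(u @ vt))
        r = u @ np.diag(c) @ vt
        c_yy = float(p1 @ (yh ** 2).sum(axis=1))
        c_xx = float(pt1 @ (xh ** 2).sum(axis=1))
        tr_sc = float((s_vals * c).sum())  # = tr(R A^T) at the optimum
        if self.estimate_scale:
            s = tr_sc / c_yy
            sigma2 = (c_xx - s * tr_sc) / (n_p * 3.0)
        else:
            s = 1.0
            sigma2 = (c_xx - 2.0 * tr_sc + c_yy) / (n_p * 3.0)
        self._r = r
        self._s = s
        self._t = mu_x - s * r @ mu_y
        return sigma2

    def _finalize(self, mu_x, mu_y):
        self.rotation_ = self._r
        self.scale_ = float(self._s)
        self.translation_ = self._t + mu_x - self._s * self._r @ mu_y
        self.transform_ = RigidTransform(rotation=self.rotation_,
                                         translation=self.translation_,
                                         scale=self.scale_)


class AffineCPD(_BaseCPD):
    """Affine coherent point drift (closed-form linear M-step)."""

    def _init_state(self, x, y):
        self._b = np.eye(3)
        self._t = np.zeros(3)

    def _transform_centered(self, y):
        return y @ self._b.T + self._t

    def _m_step(self, x, y, p):
        n_p = p.sum()
        p1 = p.sum(axis=1)
        pt1 = p.sum(axis=0)
        mu_x = (pt1 @ x) / n_p
        mu_y = (p1 @ y) / n_p
        xh = x - mu_x
        yh = y - mu_y
        a = xh.T @ p.T @ yh
        g = yh.T @ (p1[:, None] * yh)
        try:
            b = np.linalg.solve(g.T, a.T).T
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular normal equations in affine M-step") from exc
        c_xx = float(pt1 @ (xh ** 2).sum(axis=1))
        sigma2 = (c_xx - float(np.trace(a @ b.T))) / (n_p * 3.0)
        self._b = b
        self._t = mu_x - b @ mu_y
        return sigma2

    def _finalize(self, mu_x, mu_y):
        self.matrix_ = self._b
        self.translation_ = self._t + mu_x - self._b @ mu_y
        self.transform_ = AffineTransform(matrix=self.matrix_,
                                          translation=self.translation_)


class NonrigidCPD(_BaseCPD):
    """Coherent (Gaussian-kernel) nonrigid point drift.

    The displacement field is ``v(y) = G(y, Y) @ W`` with Gaussian kernel
    bandwidth ``beta``; ``lam`` penalizes incoherent motion (``lam -> inf``
    recovers zero displacement).  Run a rigid pass first for global
    pre-alignment; this stage refines residual smooth deformation.
    """

    _centers_clouds = False

    def __init__(self, beta: float = 2.0, lam: float = 2.0, max_iter: int = 50,
                 w: float = 0.0, tol: float = 1e-6):
        super().__init__(max_iter=max_iter, w=w, tol=tol)
        self.beta = beta
        self.lam = lam

    def _init_state(self, x, y):
        if self.beta <= 0 or self.lam <= 0:
            raise ValueError("beta and lam must be positive")
        diff2 = ((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
        self._g = np.exp(-diff2 / (2.0 * self.beta ** 2))
        self._w_mat = np.zeros_like(y)

    def _transform_centered(self, y):
        return y + self._g @ self._w_mat

    def _m_step(self, x, y, p):
        n_p = p.sum()
        p1 = p.sum(axis=1)
        pt1 = p.sum(axis=0)
        sigma2_prev = self.sigma2_trace_[-1] if self.sigma2_trace_ else _initial_sigma2(x, y)
        lhs = (p1[:, None] * self._g) + self.lam * sigma2_prev * np.eye(y.shape[0])
        rhs = p @ x - p1[:, None] * y
        self._w_mat = np.linalg.solve(lhs, rhs)
        ty = y + self._g @ self._w_mat
        c_xx = float(pt1 @ (x ** 2).sum(axis=1))
        cross = float(np.sum((p @ x) * ty))
        c_tt = float(p1 @ (ty ** 2).sum(axis=1))
        return (c_xx - 2.0 * cross + c_tt) / (n_p * 3.0)

    def _finalize(self, mu_x, mu_y):
        # displacement field lives on the centered source frame; keep the
        # centroids so transform() can reproduce the centering
        self.mu_x_ = mu_x
        self.mu_y_ = mu_y

    def fit(self, source, target):
        y_orig = _as_points(source)
        super().fit(source, target)
        self.anchors_ = y_orig.copy()
        self.weights_ = self._w_mat.copy()
        self.displacements_ = self._g @ self._w_mat
        self.transform_ = None  # nonparametric; use .transform()
        return self

    def transform(self, points):
        pts = _as_points(points)
        diff2 = ((pts[:, None, :] - self.anchors_[None, :, :]) ** 2).sum(axis=2)
        g = np.exp(-diff2 / (2.0 * self.beta ** 2))
        return pts + g @ self.weights_

    def fit_result(self, source, target) -> RegistrationResult:
        self.fit(source, target)
        return RegistrationResult(
            transform=None,
            iterations=self.n_iter_,
            sigma2_trace=list(self.sigma2_trace_),
            objective_trace=list(self.objective_trace_),
            converged=self.converged_,
            w=self.w,
        )


def rigid_cpd(source, target, max_iter: int = 50, w: float = 0.0,
              tol: float = 1e-6, estimate_scale: bool = True) -> RegistrationResult:
    """Rigid CPD mapping source -> target; see :class:`RigidCPD`."""
    est = RigidCPD(max_iter=max_iter, w=w, tol=tol, estimate_scale=estimate_scale)
    return est.fit_result(source, target)


def affine_cpd(source, target, max_iter: int = 50, w: float = 0.0,
               tol: float = 1e-6) -> RegistrationResult:
    est = AffineCPD(max_iter=max_iter, w=w, tol=tol)
    return est.fit_result(source, target)


def nonrigid_register(source, target, beta: float = 2.0, lam: float = 2.0,
                      max_iter: int = 50, w: float = 0.0, tol: float = 1e-6):
    """Nonrigid CPD; returns (RegistrationResult, fitted NonrigidCPD)."""
    est = NonrigidCPD(beta=beta, lam=lam, max_iter=max_iter, w=w, tol=tol)
    res = est.fit_result(source, target)
    return res, est


def apply_transform(pc: PointCloud, transform: SpatialTransform) -> PointCloud:
    """Forward-map all points of a cloud through a transform."""
    units = getattr(transform, "units", None)
    if units is not None and units != pc.space:
        raise ValueError(f"space mismatch: cloud is {pc.space!r}, transform {units!r}")
    return PointCloud(points=transform.apply(pc.points), space=pc.space,
                      grid_step_nm=pc.grid_step_nm, source=pc.source)
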