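"""Rigid point-set alignment and iterative 2D-3D keypoint correction.

The rotation between two matched 3D point sets minimising the (weighted)
sum of squared distances has a closed form: centre both sets, take the SVD
of the weighted cross-covariance, and recompose with a determinant
correction that forbids reflections. On top of that solver sits the
correction loop: decoded 2D keypoints are lifted to 3D with per-joint
depths (unknown under an orthographic camera), the body-prior skeleton is
rigidly aligned onto the lifted set with weights ``w_i = 1/c_i`` from the
decoder's uncertainties, the depths are refreshed from the aligned prior,
and after a few sweeps the prior's projection replaces the noisy 2D input.
Joints with diffuse votes (occluded, dark) barely influence the fit and are
effectively re-synthesised from body structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import UNCERTAINTY_FLOOR, PoseEstimate2D
from .skeleton import Skeleton3D


@dataclass(frozen=True)
class EuclideanTransform:
    """Proper rigid motion: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).ravel()
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("need a 3x3 rotation and a 3-vector translation")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must be proper orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class WeightVector:
    """Per-joint positive weights, the reciprocals of floored uncertainties."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).ravel()
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be finite and strictly positive")
        object.__setattr__(self, "w", w)

    @classmethod
    def from_uncertainties(
        cls, c: np.ndarray, floor: float = UNCERTAINTY_FLOOR
    ) -> "WeightVector":
        return cls(w=1.0 / np.maximum(np.asarray(c, dtype=float), floor))


@dataclass
class CorrectionResult:
    """Output of the iterative 2D-3D correction."""

    corrected2d: np.ndarray
    depths: np.ndarray
    transform: EuclideanTransform
    residuals: np.ndarray
    iterations: int


def _as_weights(w, k: int) -> np.ndarray:
    if w is None:
        return np.ones(k)
    if isinstance(w, WeightVector):
        w = w.w
    w = np.asarray(w, dtype=float).ravel()
    if w.shape != (k,):
        raise ValueError(f"need {k} weights, got {w.shape}")
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and strictly positive")
    return w


def kabsch(
    P: np.ndarray, Q: np.ndarray, w: WeightVector | np.ndarray | None = None
) -> EuclideanTransform:
    """Optimal proper rigid motion taking P onto Q in weighted least squares.

    Minimises ``sum_i (1/2) w_i ||R p_i + t - q_i||^2``. Both sets are
    centred at their weighted centroids, so the optimal translation maps
    P's centroid onto Q's. The rotation comes from the SVD of the weighted
    cross-covariance ``C = sum_i w_i q~_i p~_i^T`` (3x3; at uniform weights
    this is the plain cross-covariance, so weighted and unweighted solvers
    agree exactly): ``C = U S V^T`` gives ``R = U D V^T`` with
    ``D = diag(1, 1, det(U V^T))`` forcing ``det R = +1`` — the
    unconstrained optimum can be a reflection, which is anatomically
    invalid for a body skeleton.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("P and Q must both be (k, 3) with k >= 3")
    wv = _as_weights(w, P.shape[0])
    wv = wv / wv.max()  # scale-free objective; uniform weights become exactly 1
    wn = wv / wv.sum()
    pbar = wn @ P
    qbar = wn @ Q
    Pc = P - pbar
    Qc = Q - qbar
    C = (Qc * wv[:, None]).T @ Pc
    U, S, Vt = np.linalg.svd(C)
    if S[1] <= max(S[0], 1.0) * 1e-12:
        raise ValueError("degenerate configuration: cross-covariance rank < 2")
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return EuclideanTransform(rotation=R, translation=qbar - R @ pbar)


def alignment_residual(
    P: np.ndarray,
    Q: np.ndarray,
    w: WeightVector | np.ndarray | None,
    T: EuclideanTransform,
) -> float:
    """Weighted objective ``sum_i (1/2) w_i ||R p_i + t - q_i||^2``."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    wv = _as_weights(w, P.shape[0])
    diff = T.apply(P) - Q
    return float(0.5 * np.sum(wv * (diff**2).sum(axis=1)))


def lift_keypoints(points2d: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Orthographic back-projection: row i becomes ``(u_i, v_i, z_i)``."""
    pts = np.asarray(points2d, dtype=float)
    z = np.asarray(depths, dtype=float).ravel()
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != z.size:
        raise ValueError("points2d must be (k, 2) with matching depths")
    return np.column_stack([pts, z])


def initialize_depths(Y: np.ndarray, q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Depth initialisation by weighted planar factorisation.

    Solves the 2x3 orthographic camera ``M`` minimising
    ``sum_i w_i ||M q_i - y_i||^2`` (both sets centred), reads the scale off
    the row norms and the viewing axis off the row cross product, and
    returns ``z_i = s * q_i . r3``. On exact orthographic data this is the
    exact depth (up to the global mirror sign); on noisy data it lands close
    enough for the rigid sweeps to converge in a few iterations. Falls back
    to zero depths if the factorisation is degenerate.
    """
    sw = np.sqrt(w)[:, None]
    M, *_ = np.linalg.lstsq(sw * q, sw * Y, rcond=None)
    M = M.T  # 2x3
    s = 0.5 * (np.linalg.norm(M[0]) + np.linalg.norm(M[1]))
    r3 = np.cross(M[0], M[1])
    n = np.linalg.norm(r3)
    if n < 1e-12 or s < 1e-12:
        return np.zeros(len(Y))
    return s * (q @ (r3 / n))


def iterative_correction(
    p2d: PoseEstimate2D | np.ndarray,
    q3d: Skeleton3D,
    n_iter: int = 3,
    weights: WeightVector | np.ndarray | None = None,
    uncertainty_floor: float = UNCERTAINTY_FLOOR,
    blend: bool = False,
) -> CorrectionResult:
    """Correct 2D keypoints against the normalized 3D body prior.

    Each sweep lifts the (centred) 2D input with the current depths,
    normalises the lifted cloud to zero weighted centroid and unit weighted
    pooled std (so the rotation-only alignment never fights a scale
    mismatch), solves the weighted rigid alignment of the prior onto the
    lifted cloud, and refreshes the depths from the aligned prior's z. The
    recorded residual per sweep is the weighted objective restricted to the
    (u, v) components, in the normalised frame. The corrected output
    replaces the input (u, v) with the aligned prior's projection, mapped
    back to input units. ``n_iter`` defaults to 3 sweeps, which suffices on
    top of the factorisation depth initialisation.

    With ``blend=True`` the replacement is a per-joint convex combination
    keyed by uncertainty, ``lam_i = c_i / (1 + c_i)``: confident joints keep
    their decoded position, uncertain ones take the prior's.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not q3d.normalized:
        raise ValueError("q3d must be normalized (zero centroid, unit pooled std)")
    if isinstance(p2d, PoseEstimate2D):
        Y0 = p2d.coords()
        c_scalar = p2d.scalar_uncertainties(floor=uncertainty_floor)
        if weights is None:
            weights = WeightVector.from_uncertainties(c_scalar, floor=uncertainty_floor)
    else:
        Y0 = np.asarray(p2d, dtype=float)
        c_scalar = None
    k = Y0.shape[0]
    if Y0.shape != (k, 2) or k != q3d.k:
        raise ValueError("2D set and 3D prior must share the joint count")
    w = _as_weights(weights, k)
    wn = w / w.sum()
    centre2d = wn @ Y0
    Y = Y0 - centre2d
    if np.sqrt(np.mean(Y**2)) < 1e-12:
        raise ValueError("degenerate 2D configuration: zero spread")
    q = q3d.points
    z = initialize_depths(Y, q, w)
    residuals = np.empty(n_iter)
    for it in range(n_iter):
        X = lift_keypoints(Y, z)
        c = wn @ X
        beta = np.sqrt((wn @ ((X - c) ** 2).sum(axis=1)) / 3.0)
        Xn = (X - c) / beta
        T = kabsch(q, Xn, w)
        aligned = T.apply(q)
        residuals[it] = 0.5 * np.sum(w[:, None] * (aligned[:, :2] - Xn[:, :2]) ** 2)
        z = beta * aligned[:, 2] + c[2]
    corrected = beta * aligned[:, :2] + c[:2] + centre2d
    if blend:
        if c_scalar is None:
            raise ValueError("blend requires decoded uncertainties")
        lam = (c_scalar / (1.0 + c_scalar))[:, None]
        corrected = lam * corrected + (1.0 - lam) * Y0
    return CorrectionResult(
        corrected2d=corrected,
        depths=z,
        transform=T,
        residuals=residuals,
        iterations=n_iter,
    )
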