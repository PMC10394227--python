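"""Body shape/pose parameterisation and the training loss terms.

Shape is a 10-vector of unitless coefficients (the openly released leading
coefficients of a statistical body-shape space; values typically fall in
(-1.5, 1.5)). Pose is one unit quaternion per skeleton joint, scalar-last:
``(x' sin(a/2), y' sin(a/2), z' sin(a/2), cos(a/2))`` for a rotation by
angle ``a`` about the unit axis ``(x', y', z')``. Quaternions avoid the
gimbal ambiguity of Euler angles and make the pose loss a plain L1 with a
unit-norm regularizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class ShapeParams:
    """Shape coefficients beta (length 10, unitless)."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float).ravel()
        if not np.all(np.isfinite(b)):
            raise ValueError("shape coefficients must be finite")
        object.__setattr__(self, "beta", b)

    @classmethod
    def zeros(cls, n: int = 10) -> "ShapeParams":
        return cls(beta=np.zeros(n))


@dataclass(frozen=True)
class AxisAngle:
    """Rotation by ``angle`` (radians, in (-pi, pi]) about a unit ``axis``."""

    axis: np.ndarray
    angle: float

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float).ravel()
        if a.shape != (3,):
            raise ValueError("axis must be a 3-vector")
        if abs(np.linalg.norm(a) - 1.0) > 1e-6:
            raise ValueError("axis must have unit norm")
        object.__setattr__(self, "axis", a)


@dataclass
class PoseParams:
    """One scalar-last unit quaternion per joint, ``(k, 4)``."""

    quaternions: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternions, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError("quaternions must have shape (k, 4)")
        self.quaternions = q

    def __len__(self) -> int:
        return self.quaternions.shape[0]

    @classmethod
    def identity(cls, k: int) -> "PoseParams":
        q = np.zeros((k, 4))
        q[:, 3] = 1.0
        return cls(quaternions=q)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite training objective and its regularizers."""

    lambda_shape: float = 0.2
    lambda_pose: float = 0.25
    lambda_smpl: float = 0.15
    lambda_det: float = 0.4
    lambda_kb: float = 0.3
    omega_c: float = 0.2
    omega_p: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "lambda_shape",
            "lambda_pose",
            "lambda_smpl",
            "lambda_det",
            "lambda_kb",
            "omega_c",
            "omega_p",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def axis_angle_to_quaternion(r: AxisAngle) -> np.ndarray:
    """Scalar-last quaternion of an axis-angle rotation.

    The scalar part is kept non-negative (canonical hemisphere of the
    (q, -q) double cover) so that the L1 pose loss compares like with like.
    """
    half = 0.5 * r.angle
    q = np.empty(4)
    q[:3] = r.axis * np.sin(half)
    q[3] = np.cos(half)
    if q[3] < 0:
        q = -q
    return q


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    """Proper orthogonal 3x3 matrix of a scalar-last quaternion."""
    q = np.asarray(q, dtype=float).ravel()
    if q.shape != (4,):
        raise ValueError("quaternion must be a 4-vector")
    n = np.linalg.norm(q)
    if n < 1e-9:
        raise ValueError("near-zero quaternion has no defined rotation")
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {n} too far from 1")
    return Rotation.from_quat(q / n).as_matrix()


def rotation_to_axis_angle(rot: np.ndarray) -> AxisAngle:
    """Inverse of the quaternion chain, for round-trip checks."""
    rv = Rotation.from_matrix(np.asarray(rot, dtype=float)).as_rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        return AxisAngle(axis=np.array([0.0, 0.0, 1.0]), angle=0.0)
    return AxisAngle(axis=rv / angle, angle=angle)


def shape_loss(beta: ShapeParams, beta_hat: ShapeParams) -> float:
    """Smooth-L1 shape loss with the quadratic region widened to |d| <= 1.5.

    f(d) = (2/9) d^2 inside, (2/3)|d| - 0.5 outside; the two branches meet
    with matching value and slope at |d| = 1.5, matching the typical spread
    of the shape coefficients.
    """
    if beta.beta.shape != beta_hat.beta.shape:
        raise ValueError("shape parameter lengths differ")
    d = np.abs(beta.beta - beta_hat.beta)
    inner = (2.0 / 9.0) * d**2
    outer = (2.0 / 3.0) * d - 0.5
    return float(np.sum(np.where(d <= 1.5, inner, outer)))


def pose_loss(theta: PoseParams, theta_hat: PoseParams, omega_p: float = 1.0) -> float:
    """Per-joint L1 quaternion loss plus a unit-norm regularizer.

    Each joint contributes ``||q - q_hat||_1 + omega_p * |1 - ||q||_2^2|``;
    the regularizer pins predictions to the unit sphere where quaternions
    represent rotations. Zero exactly when every joint matches elementwise
    and is unit-norm.
    """
    if len(theta) != len(theta_hat):
        raise ValueError("pose parameter joint counts differ")
    q, qh = theta.quaternions, theta_hat.quaternions
    l1 = np.abs(q - qh).sum(axis=1)
    reg = np.abs(1.0 - (q**2).sum(axis=1))
    return float(np.sum(l1 + omega_p * reg))


def smpl_keypoint_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sum of squared 3D keypoint coordinate errors."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.sum((pred - truth) ** 2))


def total_loss(
    l_shape: float,
    l_pose: float,
    l_smpl: float,
    l_kb: float,
    l_det: float,
    w: LossWeights | None = None,
) -> float:
    """Weighted sum of all component losses.

    The detection loss is supplied externally (the detector itself is not
    part of this package).
    """
    w = w or LossWeights()
    comps = (l_shape, l_pose, l_smpl, l_kb, l_det)
    if not all(np.isfinite(c) for c in comps):
        raise ValueError("loss components must be finite")
    return (
        w.lambda_shape * l_shape
        + w.lambda_pose * l_pose
        + w.lambda_smpl * l_smpl
        + w.lambda_kb * l_kb
        + w.lambda_det * l_det
    )
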