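"""Voting decoder for per-joint heatmaps.

A joint's heatmap is an ``h x w`` grid of responses. The decoder collapses
the grid onto each image axis (column sums and row sums), softmaxes the
resulting marginal vote vector, and reads the coordinate off as the
expectation of the position index under that vote distribution. The standard
deviation of the same distribution is the per-axis localisation uncertainty:
a concentrated vote means a confident joint, a diffuse vote (occlusion, low
light, noise) means an uncertain one.

Positions are enumerated 1..n internally; file I/O converts to 0-based pixel
coordinates at the boundary (:mod:`poselift.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

#: Lower clamp applied to uncertainties before any division (grid units).
#: Keeps the Gaussian negative log-likelihood and the alignment weights
#: w_i = 1/c_i finite when a vote collapses onto a single cell.
UNCERTAINTY_FLOOR = 1e-3


@dataclass(frozen=True)
class Heatmap:
    """One joint's response grid, stored row-major as ``(h, w)``.

    Values may be negative (raw network outputs); the softmax in the vote
    handles arbitrary offsets. Non-finite values are rejected.
    """

    values: np.ndarray
    joint_id: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"heatmap must be at least 2x2, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("heatmap contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def w(self) -> int:
        return self.values.shape[1]

    @property
    def h(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class JointEstimate2D:
    """Decoded subpixel joint location with per-axis uncertainties.

    ``u`` runs along columns, ``v`` along rows, both in 1-based grid units.
    """

    u: float
    v: float
    c_u: float
    c_v: float

    @property
    def c(self) -> float:
        """Pooled scalar uncertainty: arithmetic mean of the two axes."""
        return 0.5 * (self.c_u + self.c_v)


@dataclass
class PoseEstimate2D:
    """Ordered joint estimates for one skeleton (order fixed by the tree)."""

    joints: list[JointEstimate2D] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.joints)

    def coords(self) -> np.ndarray:
        """``(k, 2)`` array of (u, v) coordinates."""
        return np.array([[j.u, j.v] for j in self.joints], dtype=float)

    def uncertainties(self) -> np.ndarray:
        """``(k, 2)`` array of (c_u, c_v)."""
        return np.array([[j.c_u, j.c_v] for j in self.joints], dtype=float)

    def scalar_uncertainties(self, floor: float = UNCERTAINTY_FLOOR) -> np.ndarray:
        """Per-joint pooled uncertainty c_i, clamped from below at *floor*."""
        c = np.array([j.c for j in self.joints], dtype=float)
        return np.maximum(c, floor)


def marginalize(hm: Heatmap) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate heatmap mass along each axis.

    Returns ``(z_u, z_v)`` where ``z_u[j]`` is the sum of column ``j`` over
    all rows (length w) and ``z_v[j]`` the sum of row ``j`` over all columns
    (length h). Both share the grid's total mass.
    """
    z_u = hm.values.sum(axis=0)
    z_v = hm.values.sum(axis=1)
    return z_u, z_v


def vote_distribution(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized vote weights and their 1-based enumeration positions."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("vote vector must be 1-D with at least 2 entries")
    if not np.all(np.isfinite(z)):
        raise ValueError("vote vector contains non-finite values")
    return softmax(z), np.arange(1, z.size + 1, dtype=float)


def soft_vote(z: np.ndarray) -> tuple[float, float]:
    """Softmax vote over a marginal vector.

    With ``z* = softmax(z)`` and enumeration ``e = [1, ..., n]`` the
    coordinate is the expectation ``sum z*_j e_j`` and the uncertainty the
    standard deviation ``sqrt(sum z*_j (e_j - coord)^2)`` of the vote
    distribution over positions.
    """
    p, e = vote_distribution(z)
    coord = float(p @ e)
    var = float(p @ (e - coord) ** 2)
    return coord, float(np.sqrt(max(var, 0.0)))


def decode(heatmaps: list[Heatmap]) -> PoseEstimate2D:
    """Decode a k-channel heatmap stack into joint estimates.

    All maps must share one grid shape. Each joint gets an independent vote
    per axis from its marginalised map.
    """
    if not heatmaps:
        raise ValueError("no heatmaps to decode")
    shape = heatmaps[0].values.shape
    joints = []
    for hm in heatmaps:
        if hm.values.shape != shape:
            raise ValueError(
                f"inconsistent heatmap shapes: {hm.values.shape} vs {shape}"
            )
        z_u, z_v = marginalize(hm)
        u, c_u = soft_vote(z_u)
        v, c_v = soft_vote(z_v)
        joints.append(JointEstimate2D(u=u, v=v, c_u=c_u, c_v=c_v))
    return PoseEstimate2D(joints=joints)


def argmax_decode(hm: Heatmap) -> tuple[float, float]:
    """Integer argmax baseline (test comparator only, no subpixel refinement)."""
    r, c = np.unravel_index(np.argmax(hm.values), hm.values.shape)
    return float(c + 1), float(r + 1)


def kblock_loss(
    estimates: PoseEstimate2D,
    truth: np.ndarray,
    omega_c: float = 0.2,
    floor: float = UNCERTAINTY_FLOOR,
) -> float:
    """Gaussian negative log-likelihood loss of the voting decoder.

    Each axis of each joint contributes ``log(sqrt(2 pi) c) +
    (x - x_hat)^2 / (2 c^2)``, i.e. the exact negative log of a Gaussian
    error model with the decoded uncertainty as its standard deviation,
    plus a regularizer ``omega_c * 1 / (2 c^2)`` that keeps the model from
    buying loss reduction with ever-sharper (overconfident) votes.
    ``omega_c`` defaults to 0.2.
    """
    truth = np.asarray(truth, dtype=float)
    k = len(estimates)
    if truth.shape != (k, 2):
        raise ValueError(f"truth must have shape ({k}, 2), got {truth.shape}")
    pred = estimates.coords()
    c = np.maximum(estimates.uncertainties(), floor)
    if np.any(c <= 0):
        raise ValueError("uncertainties must be positive after clamping")
    resid2 = (pred - truth) ** 2
    nll = np.log(np.sqrt(2.0 * np.pi) * c) + resid2 / (2.0 * c**2)
    reg = omega_c / (2.0 * c**2)
    total = float(np.sum(nll) + np.sum(reg))
    if not np.isfinite(total):
        raise ValueError("non-finite loss")
    return total
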