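"""Synthetic kinematic body model and scene generator.

This module is the fixture factory for the whole toolkit. It stands in for
a statistical body model: a rooted kinematic tree whose bone lengths depend
linearly on the 10 shape coefficients, posed by per-joint quaternions, then
orthographically projected and rendered into per-joint Gaussian heatmaps
with optional additive noise and per-joint occlusion attenuation.

Coordinate conventions: 3D joints live in arbitrary length units until
:func:`normalize_points` removes the centroid and rescales the pooled
standard deviation to one. 2D grid coordinates are 1-based (column ``u``,
row ``v``), matching the decoder's enumeration.

Heatmap rendering is parameterised by the *peak marginal logit* (``gain``):
the bump amplitude is ``gain / (sigma * sqrt(2 pi))`` so that the column or
row sum over an amplitude-scaled Gaussian peaks at ``gain`` regardless of
``sigma``. The softmax vote treats heatmap mass as logits, so this is the
quantity that controls how concentrated the vote is; a fixed peak amplitude
would make narrow bumps decode *worse* (their marginal mass vanishes and
the vote goes uniform).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .body import PoseParams, ShapeParams
from .decoder import Heatmap

#: Fixed seed of the synthetic shape basis; part of the model definition,
#: not a knob.
_SHAPE_BASIS_SEED = 1402

#: Default peak marginal logit of a rendered bump (see module docstring).
DEFAULT_GAIN = 10.0

#: Amplitude attenuation applied to occluded joints: their bump survives at
#: a tenth of the gain, so the vote is diffuse and the decoded uncertainty
#: high, rather than the joint disappearing outright.
OCCLUSION_ATTENUATION = 0.1


@dataclass
class KinematicTree:
    """Rooted joint hierarchy with shape-dependent bone lengths.

    ``parent[j]`` is the parent joint index (-1 for the root). Per-joint
    arrays carry a zero row for the root. ``shape_basis`` maps the shape
    vector beta to additive bone-length offsets; it is scaled so offsets
    stay within 30% of the base length over beta in [-1.5, 1.5]^10, keeping
    every bone positive.
    """

    parent: np.ndarray
    rest_directions: np.ndarray
    base_lengths: np.ndarray
    shape_basis: np.ndarray
    joint_names: list[str] = field(default_factory=list)
    version: str = "1"

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.rest_directions = np.asarray(self.rest_directions, dtype=float)
        self.base_lengths = np.asarray(self.base_lengths, dtype=float)
        self.shape_basis = np.asarray(self.shape_basis, dtype=float)
        k = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        # reject cycles / forward references by walking to the root
        for j in range(k):
            seen, p = set(), j
            while p >= 0:
                if p in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(p)
                p = int(self.parent[p])

    @property
    def k(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def bone_lengths(self, beta: ShapeParams) -> np.ndarray:
        """Per-joint bone length under shape *beta* (root entry 0)."""
        lengths = self.base_lengths + self.shape_basis @ beta.beta
        lengths[self.root] = 0.0
        nonroot = self.parent >= 0
        if np.any(lengths[nonroot] <= 0):
            raise ValueError("non-positive bone length under this shape")
        return lengths

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "joint_names": self.joint_names,
                "parent": self.parent.tolist(),
                "rest_directions": self.rest_directions.tolist(),
                "base_lengths": self.base_lengths.tolist(),
                "shape_basis": self.shape_basis.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "KinematicTree":
        d = json.loads(text)
        return cls(
            parent=d["parent"],
            rest_directions=d["rest_directions"],
            base_lengths=d["base_lengths"],
            shape_basis=d["shape_basis"],
            joint_names=list(d.get("joint_names", [])),
            version=str(d.get("version", "1")),
        )


@dataclass
class Skeleton3D:
    """A ``(k, 3)`` joint set, optionally centroid-free with pooled std 1."""

    points: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (k, 3)")

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass
class SyntheticScene:
    """One generated trial: posed body, projection, heatmaps, corruption."""

    truth3d: Skeleton3D
    truth2d: np.ndarray
    heatmaps: list[Heatmap]
    occluded: np.ndarray
    noise_sigma: float
    seed: int
    sigma: float = 1.5
    scale: float = 1.0
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    beta: ShapeParams | None = None
    theta: PoseParams | None = None
    out_of_frame: bool = False


# --- default body -----------------------------------------------------------

_JOINT_NAMES = [
    "pelvis", "spine", "chest", "neck", "head",
    "l_shoulder", "l_elbow", "l_wrist",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_hip", "l_knee", "l_ankle",
    "r_hip", "r_knee", "r_ankle",
]

_PARENT = [-1, 0, 1, 2, 3, 2, 5, 6, 2, 8, 9, 0, 11, 12, 0, 14, 15]

# T-pose rest directions (y up, x left, z toward the camera). Small z and
# asymmetric components keep the rest pose non-planar and chirally unique,
# which protects the alignment tests from accidental reflection symmetry.
_REST_DIRECTIONS = [
    (0.0, 0.0, 0.0),          # pelvis (root)
    (0.02, 1.0, 0.05),        # spine
    (0.0, 1.0, -0.04),        # chest
    (0.03, 1.0, 0.08),        # neck
    (0.0, 0.95, 0.12),        # head
    (1.0, 0.15, 0.05),        # l_shoulder
    (1.0, -0.05, -0.08),      # l_elbow
    (1.0, 0.0, 0.06),         # l_wrist
    (-1.0, 0.15, -0.06),      # r_shoulder
    (-1.0, -0.05, 0.07),      # r_elbow
    (-1.0, 0.0, -0.05),       # r_wrist
    (0.6, -0.8, 0.05),        # l_hip
    (0.05, -1.0, 0.08),       # l_knee
    (0.0, -1.0, -0.06),       # l_ankle
    (-0.6, -0.8, -0.05),      # r_hip
    (-0.05, -1.0, 0.07),      # r_knee
    (0.0, -1.0, 0.05),        # r_ankle
]

_BASE_LENGTHS = [
    0.0, 0.24, 0.24, 0.10, 0.16,
    0.18, 0.28, 0.25,
    0.18, 0.28, 0.25,
    0.12, 0.40, 0.40,
    0.12, 0.40, 0.40,
]


def default_tree(n_shape: int = 10) -> KinematicTree:
    """The default 17-joint body in a COCO-like ordering.

    The shape basis is a fixed seeded sparse matrix (three active
    coefficients per bone) scaled so that the worst-case length offset over
    beta in [-1.5, 1.5]^10 is 30% of the base length.
    """
    rng = np.random.default_rng(_SHAPE_BASIS_SEED)
    k = len(_PARENT)
    dirs = np.asarray(_REST_DIRECTIONS, dtype=float)
    norms = np.linalg.norm(dirs, axis=1)
    dirs[1:] /= norms[1:, None]
    basis = np.zeros((k, n_shape))
    base = np.asarray(_BASE_LENGTHS, dtype=float)
    for j in range(1, k):
        cols = rng.choice(n_shape, size=3, replace=False)
        row = rng.normal(size=3)
        row *= 0.3 * base[j] / (1.5 * np.abs(row).sum())
        basis[j, cols] = row
    return KinematicTree(
        parent=_PARENT,
        rest_directions=dirs,
        base_lengths=base,
        shape_basis=basis,
        joint_names=list(_JOINT_NAMES),
    )


# --- kinematics and camera --------------------------------------------------


def forward_kinematics(
    tree: KinematicTree, beta: ShapeParams, theta: PoseParams
) -> Skeleton3D:
    """Posed 3D joints: each bone is its shape-dependent length along the
    rest direction, rotated by the composition of all rotations from the
    root down to (and including) the joint itself. Joint 0's quaternion is
    the global body orientation."""
    if len(theta) != tree.k:
        raise ValueError(f"need {tree.k} quaternions, got {len(theta)}")
    lengths = tree.bone_lengths(beta)
    rots = Rotation.from_quat(theta.quaternions).as_matrix()
    pts = np.zeros((tree.k, 3))
    glob = [None] * tree.k
    # parents precede children in the default ordering; walk generically
    order = _topological_order(tree)
    for j in order:
        p = int(tree.parent[j])
        if p < 0:
            glob[j] = rots[j]
            continue
        glob[j] = glob[p] @ rots[j]
        pts[j] = pts[p] + glob[j] @ (lengths[j] * tree.rest_directions[j])
    return Skeleton3D(points=pts, normalized=False)


def _topological_order(tree: KinematicTree) -> list[int]:
    order, placed = [], set()
    pending = list(range(tree.k))
    while pending:
        rest = []
        for j in pending:
            p = int(tree.parent[j])
            if p < 0 or p in placed:
                order.append(j)
                placed.add(j)
            else:
                rest.append(j)
        pending = rest
    return order


def normalize_points(points: np.ndarray) -> Skeleton3D:
    """Remove the centroid and rescale the pooled standard deviation to 1.

    The pooled std is the root mean square of all 3k centred coordinates,
    so the whole point cloud — not each axis — carries unit spread.
    Idempotent, translation-invariant, rotation-equivariant.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centred = pts - pts.mean(axis=0)
    pooled = np.sqrt(np.mean(centred**2))
    if pooled < 1e-12:
        raise ValueError("degenerate point set: zero spread")
    return Skeleton3D(points=centred / pooled, normalized=True)


def project_orthographic(
    skeleton: Skeleton3D, scale: float = 1.0, offset: np.ndarray | None = None
) -> np.ndarray:
    """Orthographic camera: ``(u, v) = scale * (x, y) + offset``; z (the
    depth axis, perpendicular to the image plane) is dropped."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    offset = np.zeros(2) if offset is None else np.asarray(offset, dtype=float)
    return scale * skeleton.points[:, :2] + offset


def render_heatmaps(
    points2d: np.ndarray,
    grid: tuple[int, int] = (32, 32),
    sigma: float = 1.5,
    noise_sigma: float = 0.0,
    occluded: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    gain: float = DEFAULT_GAIN,
    attenuation: float = OCCLUSION_ATTENUATION,
) -> list[Heatmap]:
    """Render per-joint isotropic Gaussian bumps on a ``w x h`` grid.

    The bump amplitude is ``gain / (sigma sqrt(2 pi))`` so the marginal
    (column/row sum) peaks at ``gain``; occluded joints get the amplitude
    attenuated by ``attenuation``. I.i.d. Gaussian noise of std
    ``noise_sigma`` is added per cell. Deterministic given the seed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.asarray(points2d, dtype=float)
    k = pts.shape[0]
    w, h = grid
    occluded = (
        np.zeros(k, dtype=bool) if occluded is None else np.asarray(occluded, bool)
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = np.arange(1, w + 1, dtype=float)
    rows = np.arange(1, h + 1, dtype=float)
    uu, vv = np.meshgrid(cols, rows)
    amp0 = gain / (sigma * np.sqrt(2.0 * np.pi))
    out = []
    for j in range(k):
        u, v = pts[j]
        if u < 1 - 2 * sigma or u > w + 2 * sigma or v < 1 - 2 * sigma or v > h + 2 * sigma:
            warnings.warn(f"joint {j} centre ({u:.1f}, {v:.1f}) far outside grid")
        amp = amp0 * (attenuation if occluded[j] else 1.0)
        values = amp * np.exp(-((uu - u) ** 2 + (vv - v) ** 2) / (2.0 * sigma**2))
        if noise_sigma > 0:
            values = values + rng.normal(0.0, noise_sigma, size=values.shape)
        out.append(Heatmap(values=values, joint_id=j))
    return out


def sample_scene(
    tree: KinematicTree | None = None,
    beta_range: float = 1.5,
    pose_range: float = 0.5,
    noise_sigma: float = 0.0,
    occlusion_rate: float = 0.0,
    seed: int = 0,
    grid: tuple[int, int] = (32, 32),
    sigma: float = 1.5,
    gain: float = DEFAULT_GAIN,
    max_scale: float = 5.0,
) -> SyntheticScene:
    """Draw one reproducible synthetic trial.

    Shape is uniform in ``[-beta_range, beta_range]^10``; each joint gets a
    random-axis rotation with angle uniform in ``[-pose_range, pose_range]``
    radians, and the root a uniformly random global orientation. The
    normalized skeleton is projected with a per-scene scale that keeps every
    joint at least ``3 sigma + 1`` grid units from the border (capped at
    ``max_scale``), centred on the grid.
    """
    if not 0.0 <= occlusion_rate <= 1.0:
        raise ValueError("occlusion_rate must be in [0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    tree = tree or default_tree()
    rng = np.random.default_rng(seed)
    beta = ShapeParams(rng.uniform(-beta_range, beta_range, size=10))
    quats = np.zeros((tree.k, 4))
    root_q = rng.normal(size=4)
    quats[tree.root] = root_q / np.linalg.norm(root_q)
    for j in range(tree.k):
        if j == tree.root:
            continue
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-pose_range, pose_range)
        quats[j, :3] = axis * np.sin(0.5 * angle)
        quats[j, 3] = np.cos(0.5 * angle)
    theta = PoseParams(quaternions=quats)
    truth3d = normalize_points(forward_kinematics(tree, beta, theta).points)
    w, h = grid
    centre = np.array([(w + 1) / 2.0, (h + 1) / 2.0])
    margin = 3.0 * sigma + 1.0
    half = (min(w, h) - 1) / 2.0
    spread = np.abs(truth3d.points[:, :2]).max()
    scale = min(max_scale, (half - margin) / max(spread, 1e-9))
    truth2d = project_orthographic(truth3d, scale=scale, offset=centre)
    occluded = rng.uniform(size=tree.k) < occlusion_rate
    heatmaps = render_heatmaps(
        truth2d,
        grid=grid,
        sigma=sigma,
        noise_sigma=noise_sigma,
        occluded=occluded,
        seed=rng,
        gain=gain,
    )
    oob = bool(
        np.any(truth2d < 1 - 2 * sigma)
        or np.any(truth2d[:, 0] > w + 2 * sigma)
        or np.any(truth2d[:, 1] > h + 2 * sigma)
    )
    return SyntheticScene(
        truth3d=truth3d,
        truth2d=truth2d,
        heatmaps=heatmaps,
        occluded=occluded,
        noise_sigma=noise_sigma,
        seed=seed,
        sigma=sigma,
        scale=scale,
        offset=centre,
        beta=beta,
        theta=theta,
        out_of_frame=oob,
    )
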