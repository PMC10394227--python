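"""File formats, run configuration and logging.

Keypoints travel as COCO-style JSON records extended with explicit
per-axis uncertainties; the familiar ``score`` field is populated with
``1 / (1 + c)`` so downstream pose tooling that sorts by confidence keeps
working. Heatmap stacks live in HDF5 as a ``(k, h, w)`` dataset with the
generator metadata as attributes. Coordinates in files are 0-based pixel
coordinates; the decoder's 1-based enumeration is an internal convention
converted here at the boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .body import LossWeights
from .decoder import UNCERTAINTY_FLOOR, Heatmap, JointEstimate2D, PoseEstimate2D
from .skeleton import DEFAULT_GAIN, Skeleton3D, SyntheticScene

logger = logging.getLogger("poselift")

KEYPOINT_FORMAT = "poselift-keypoints-v1"


class SchemaError(ValueError):
    """A file violated the expected schema; the message names the field."""


@dataclass
class RunConfig:
    """Validated run parameters; defaults match the method's constants."""

    grid_w: int = 32
    grid_h: int = 32
    sigma: float = 1.5
    gain: float = DEFAULT_GAIN
    noise_sigma: float = 0.0
    occlusion_rate: float = 0.0
    n_iter: int = 3
    uncertainty_floor: float = UNCERTAINTY_FLOOR
    blend: bool = False
    seed: int = 0
    beta_range: float = 1.5
    pose_range: float = 0.5
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.grid_w < 2 or self.grid_h < 2:
            raise ValueError("grid must be at least 2x2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.occlusion_rate <= 1.0:
            raise ValueError("occlusion_rate must be in [0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.uncertainty_floor <= 0:
            raise ValueError("uncertainty_floor must be positive")

    @property
    def grid(self) -> tuple[int, int]:
        return (self.grid_w, self.grid_h)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    weights = raw.pop("weights", None)
    known = set(RunConfig.__dataclass_fields__) - {"weights"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if weights is not None:
        cfg.weights = LossWeights(**weights)
    return cfg


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# --- keypoint JSON ----------------------------------------------------------


def write_keypoints(
    path: str | Path,
    pose: PoseEstimate2D,
    truth: np.ndarray | None = None,
    grid: tuple[int, int] | None = None,
) -> None:
    """Write decoded joints (and optional 2D truth) as keypoint JSON.

    Internal 1-based grid coordinates become 0-based pixel coordinates.
    """
    records = []
    for jid, j in enumerate(pose.joints):
        records.append(
            {
                "joint_id": jid,
                "u": j.u - 1.0,
                "v": j.v - 1.0,
                "c_u": j.c_u,
                "c_v": j.c_v,
                "score": 1.0 / (1.0 + j.c),
            }
        )
    doc: dict = {"format": KEYPOINT_FORMAT, "keypoints": records}
    if grid is not None:
        doc["grid"] = list(grid)
    if truth is not None:
        doc["truth2d"] = (np.asarray(truth, dtype=float) - 1.0).tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_keypoints(path: str | Path) -> tuple[PoseEstimate2D, np.ndarray | None]:
    """Read keypoint JSON back into 1-based internal coordinates.

    Missing uncertainties default to a uniform 1.0 per axis; negative ones
    are rejected with the offending field named.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if doc.get("format") != KEYPOINT_FORMAT:
        raise SchemaError(f"field 'format': expected {KEYPOINT_FORMAT!r}")
    records = doc.get("keypoints")
    if not isinstance(records, list) or not records:
        raise SchemaError("field 'keypoints': must be a non-empty list")
    joints = []
    for idx, rec in enumerate(records):
        for coord in ("u", "v"):
            if coord not in rec or not isinstance(rec[coord], (int, float)):
                raise SchemaError(f"keypoints[{idx}].{coord}: missing or non-numeric")
        c_u = rec.get("c_u", 1.0)
        c_v = rec.get("c_v", 1.0)
        for name, val in (("c_u", c_u), ("c_v", c_v)):
            if not isinstance(val, (int, float)) or val < 0:
                raise SchemaError(f"keypoints[{idx}].{name}: must be a number >= 0")
        joints.append(
            JointEstimate2D(
                u=float(rec["u"]) + 1.0,
                v=float(rec["v"]) + 1.0,
                c_u=float(c_u),
                c_v=float(c_v),
            )
        )
    truth = doc.get("truth2d")
    truth_arr = None if truth is None else np.asarray(truth, dtype=float) + 1.0
    return PoseEstimate2D(joints=joints), truth_arr


# --- heatmap / scene HDF5 ---------------------------------------------------


def write_scene(path: str | Path, scene: SyntheticScene) -> None:
    """Serialise a synthetic scene: heatmaps plus ground truth and metadata."""
    with h5py.File(path, "w") as f:
        stack = np.stack([hm.values for hm in scene.heatmaps])
        f.create_dataset("heatmaps", data=stack)
        f.create_dataset("truth2d", data=scene.truth2d - 1.0)
        f.create_dataset("truth3d", data=scene.truth3d.points)
        f.create_dataset("occluded", data=scene.occluded.astype(np.uint8))
        f.attrs["sigma"] = scene.sigma
        f.attrs["noise_sigma"] = scene.noise_sigma
        f.attrs["seed"] = scene.seed
        f.attrs["scale"] = scene.scale
        f.attrs["offset"] = scene.offset


def read_scene(path: str | Path) -> SyntheticScene:
    with h5py.File(path, "r") as f:
        stack = f["heatmaps"][...]
        truth2d = f["truth2d"][...] + 1.0
        truth3d = f["truth3d"][...]
        occluded = f["occluded"][...].astype(bool)
        attrs = dict(f.attrs)
    heatmaps = [Heatmap(values=stack[j], joint_id=j) for j in range(stack.shape[0])]
    return SyntheticScene(
        truth3d=Skeleton3D(points=truth3d, normalized=True),
        truth2d=truth2d,
        heatmaps=heatmaps,
        occluded=occluded,
        noise_sigma=float(attrs.get("noise_sigma", 0.0)),
        seed=int(attrs.get("seed", 0)),
        sigma=float(attrs.get("sigma", 1.5)),
        scale=float(attrs.get("scale", 1.0)),
        offset=np.asarray(attrs.get("offset", np.zeros(2)), dtype=float),
    )


def write_correction(
    path: str | Path,
    corrected2d: np.ndarray,
    depths: np.ndarray,
    residuals: np.ndarray,
) -> None:
    """Serialise a correction result as keypoint JSON (0-based coordinates)."""
    doc = {
        "format": "poselift-correction-v1",
        "corrected2d": (np.asarray(corrected2d, dtype=float) - 1.0).tolist(),
        "depths": [float(z) for z in np.asarray(depths).ravel()],
        "residuals": [float(r) for r in np.asarray(residuals).ravel()],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_correction(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "poselift-correction-v1":
        raise SchemaError("field 'format': expected 'poselift-correction-v1'")
    return (
        np.asarray(doc["corrected2d"], dtype=float) + 1.0,
        np.asarray(doc["depths"], dtype=float),
        np.asarray(doc["residuals"], dtype=float),
    )
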