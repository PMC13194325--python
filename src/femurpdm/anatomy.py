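"""Anatomical coordinate frames, side mirroring, length standardization and
translation-only cohort alignment.

The surgically relevant frame is built from the posterior condylar axis and
the line from the condyle midpoint to the intertrochanteric crest: x̂ runs
lateral→medial along the condylar axis, ẑ points proximally toward the crest
(orthogonalized against x̂) and ŷ completes the right-handed triad.  Because
x̂ always runs lateral→medial, femoral anteversion is positive for both sides
once right femora are mirrored to left.

Alignment across a cohort is by translation only — no rotation, no scaling —
which accommodates different specimen positions/heights while preserving every
intra-shape distance exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import MeshError, OsteotomyPlane, as_mesh, cut_with_plane

REQUIRED_LANDMARKS = (
    "intertrochanteric_crest",
    "condyle_posterior_medial",
    "condyle_posterior_lateral",
    "head_seed",
    "gt_tip",
    "lt_apex",
)

FRAME_LANDMARKS = REQUIRED_LANDMARKS[:3]


class LandmarkError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) accompanying one mesh, plus the side."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    side: str = "left"

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=np.float64)
                       for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def require(self, names=FRAME_LANDMARKS) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise LandmarkError(f"missing landmarks: {missing}")

    def translated(self, offset: np.ndarray) -> "LandmarkSet":
        return LandmarkSet({k: v + offset for k, v in self.points.items()},
                           side=self.side)

    def mirrored_y(self, new_side: str | None = None) -> "LandmarkSet":
        pts = {k: v * np.array([1.0, -1.0, 1.0]) for k, v in self.points.items()}
        side = new_side if new_side is not None else \
            ("left" if self.side == "right" else "right")
        return LandmarkSet(pts, side=side)

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {"side": self.side,
                   "points": {k: list(map(float, v))
                              for k, v in self.points.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(points={k: np.array(v) for k, v in payload["points"].items()},
                   side=payload["side"])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name,x,y,z\n")
            for k, v in self.points.items():
                fh.write(f"{k},{v[0]:.9g},{v[1]:.9g},{v[2]:.9g}\n")

    @classmethod
    def from_csv(cls, path, side: str = "left") -> "LandmarkSet":
        pts = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                name, x, y, z = line.strip().split(",")
                pts[name] = np.array([float(x), float(y), float(z)])
        return cls(points=pts, side=side)


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal triad + origin (condyle midpoint)."""

    origin: np.ndarray
    x: np.ndarray  # posterior condylar axis, lateral -> medial
    y: np.ndarray  # z cross x
    z: np.ndarray  # toward the intertrochanteric crest

    def rotation(self) -> np.ndarray:
        """World->frame rotation: rows are the frame axes."""
        return np.vstack([self.x, self.y, self.z])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation().T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation() + self.origin

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"origin": self.origin.tolist(),
                       "axes": self.rotation().tolist()}, fh, indent=1)


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Construct the condyle-based anatomical frame from named landmarks.

    Transforming the landmarks into the frame places both condyle points on
    the x-axis and the intertrochanteric crest in the x-z plane.
    """
    landmarks.require(FRAME_LANDMARKS)
    med = landmarks["condyle_posterior_medial"]
    lat = landmarks["condyle_posterior_lateral"]
    crest = landmarks["intertrochanteric_crest"]
    if np.linalg.norm(med - lat) < 1e-9:
        raise LandmarkError("condyle points coincide")
    origin = 0.5 * (med + lat)
    x = (med - lat) / np.linalg.norm(med - lat)
    z0 = crest - origin
    z = z0 - (z0 @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-6 * max(np.linalg.norm(z0), 1.0) or nz < 1e-9:
        raise LandmarkError("crest is collinear with the condylar axis")
    z = z / nz
    y = np.cross(z, x)
    return AnatomicalFrame(origin=origin, x=x, y=y, z=z)


def express_in_frame(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                     frame: AnatomicalFrame | None = None,
                     ) -> tuple[trimesh.Trimesh, LandmarkSet, AnatomicalFrame]:
    """Rigidly transform mesh + landmarks into the anatomical frame."""
    if frame is None:
        frame = build_frame(landmarks)
    verts = frame.to_frame(mesh.vertices)
    lms = LandmarkSet({k: frame.to_frame(v)[0]
                       for k, v in landmarks.points.items()},
                      side=landmarks.side)
    return as_mesh(verts, mesh.faces), lms, frame


def mirror_to_left(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                   ) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Mirror a frame-expressed right femur into a left-standard one.

    A right femur expressed in its own condyle frame (x̂ lateral→medial) is
    the left geometry with the antero-posterior axis negated, so the
    standardizing reflection is across the x-z plane (y → −y).  Face winding
    is flipped to keep the signed volume positive.  Applying this to a femur
    already flagged left raises, preventing accidental double mirroring.
    """
    if landmarks.side != "right":
        raise LandmarkError("mirror_to_left requires a right-sided femur "
                            f"(got side={landmarks.side!r})")
    verts = mesh.vertices * np.array([1.0, -1.0, 1.0])
    out = as_mesh(verts, mesh.faces[:, ::-1])
    return out, landmarks.mirrored_y(new_side="left")


def standardize_length(mesh: trimesh.Trimesh, target_length: float = 150.0,
                       tol: float = 1e-6) -> trimesh.Trimesh:
    """Transverse distal cut so the proximal ẑ-extent equals ``target_length``.

    Raises if the specimen is shorter than the target; if it is already the
    target length (within ``tol``) the input is returned with a warning.
    """
    zmin, zmax = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    extent = zmax - zmin
    if extent < target_length - tol:
        raise MeshError(f"specimen extent {extent:.2f} mm is shorter than the "
                        f"target {target_length} mm")
    if extent <= target_length + tol:
        warnings.warn("specimen already at target length; returning unchanged")
        return mesh
    plane = OsteotomyPlane(point=[0.0, 0.0, zmax - target_length],
                           normal=[0.0, 0.0, 1.0])
    return cut_with_plane(mesh, plane, cap=True)


def _cut_face_centroid(mesh: trimesh.Trimesh, slab: float = 0.5) -> np.ndarray:
    zmin = mesh.vertices[:, 2].min()
    sel = mesh.vertices[:, 2] <= zmin + slab
    return mesh.vertices[sel].mean(axis=0)


def anchor_point(mesh: trimesh.Trimesh, landmarks: LandmarkSet | None = None,
                 anchor: str = "cut_face_centroid") -> np.ndarray:
    """Reference point used for translation-only alignment."""
    if anchor == "cut_face_centroid":
        return _cut_face_centroid(mesh)
    if anchor == "centroid":
        return mesh.vertices.mean(axis=0)
    if anchor == "crest":
        if landmarks is None:
            raise LandmarkError("crest anchor needs landmarks")
        return landmarks["intertrochanteric_crest"]
    raise ValueError(f"unknown anchor {anchor!r}")


def align_translation_only(meshes: list[trimesh.Trimesh],
                           landmark_sets: list[LandmarkSet] | None = None,
                           anchor: str = "cut_face_centroid",
                           ) -> tuple[list[trimesh.Trimesh], np.ndarray]:
    """Translate each frame-expressed shape so a common anchor coincides.

    The anchor (default: centroid of the capped distal cut face, which is
    insensitive to head/trochanter size) is moved to the origin for every
    shape.  Returns the translated meshes and the per-shape offsets applied,
    so callers can shift the matching landmarks identically.  No rotation or
    scaling is applied: intra-shape distances are untouched.
    """
    if not meshes:
        return [], np.zeros((0, 3))
    offsets = []
    out = []
    for i, mesh in enumerate(meshes):
        lms = landmark_sets[i] if landmark_sets else None
        a = anchor_point(mesh, lms, anchor)
        offsets.append(-a)
        out.append(as_mesh(mesh.vertices - a, mesh.faces))
    return out, np.array(offsets)
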