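"""Point distribution model: PCA of corresponded shapes.

The model is the classic linear statistical shape model: the cohort's mean
shape M̄ (the reference geometry), orthonormal eigenmodes φ_i of the shape
covariance and their eigenvalues λ_i (mm², the variance along each mode).
New shapes are synthesized as

    x(w) = M̄ + Σ_i w_i √λ_i φ_i

with the weights w_i in standard-deviation units; ±3 SD along one mode
visualizes that mode's anatomy.  The decomposition uses the thin SVD of the
centered S x 3N data matrix (numerically stable for 3N >> S) with sample
(S−1) normalization, and each mode's sign is fixed deterministically by
making its largest-magnitude training coefficient positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .correspondence import CorrespondedShape, data_matrix


class ModelError(ValueError):
    pass


@dataclass
class ShapeModel:
    mean: np.ndarray                # (3N,)
    modes: np.ndarray               # (k, 3N) orthonormal rows
    eigenvalues: np.ndarray         # (k,) mm^2, non-increasing
    n_shapes: int
    template_id: str = "template"
    metadata: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_points(self) -> int:
        return len(self.mean) // 3

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            raise ModelError("model carries no variance")
        return self.eigenvalues / tot

    def validate(self) -> None:
        g = self.modes @ self.modes.T
        if not np.allclose(g, np.eye(self.n_modes), atol=1e-8):
            raise ModelError("modes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ModelError("eigenvalues are not non-increasing")
        if abs(self.variance_fractions.sum() - 1.0) > 1e-9:
            raise ModelError("variance fractions do not sum to 1")

    # -- persistence -------------------------------------------------------
    def to_hdf5(self, group) -> None:
        for name, data in (("mean", self.mean), ("modes", self.modes),
                           ("eigenvalues", self.eigenvalues)):
            group.create_dataset(name, data=data, track_times=False)
        group.attrs["n_shapes"] = self.n_shapes
        group.attrs["template_id"] = self.template_id
        for k, v in self.metadata.items():
            group.attrs[f"meta_{k}"] = v

    @classmethod
    def from_hdf5(cls, group) -> "ShapeModel":
        meta = {k[5:]: group.attrs[k] for k in group.attrs if
                k.startswith("meta_")}
        return cls(mean=group["mean"][...], modes=group["modes"][...],
                   eigenvalues=group["eigenvalues"][...],
                   n_shapes=int(group.attrs["n_shapes"]),
                   template_id=str(group.attrs["template_id"]),
                   metadata=meta)


def fit_ssm(shapes: list[CorrespondedShape] | np.ndarray,
            template_id: str | None = None) -> ShapeModel:
    """Fit the PCA shape model to a cohort of corresponded shapes.

    Accepts either CorrespondedShape objects or a raw S x 3N matrix.  Modes
    are ranked by descending eigenvalue; trailing numerically-zero modes are
    dropped so the mode count never exceeds min(S−1, 3N).
    """
    if isinstance(shapes, np.ndarray):
        X = np.asarray(shapes, dtype=np.float64)
        tid = template_id or "template"
    else:
        X = data_matrix(shapes)
        tid = template_id or (shapes[0].template_id if shapes else "template")
    S = len(X)
    if S < 2:
        raise ModelError(f"need >= 2 shapes to fit a model, got {S}")
    mean = X.mean(axis=0)
    C = X - mean
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    lam = s ** 2 / (S - 1)
    rank = min(S - 1, X.shape[1])
    lam, U, s, Vt = lam[:rank], U[:, :rank], s[:rank], Vt[:rank]
    keep = lam > max(lam[0], 0.0) * 1e-12 if lam.size else np.array([], bool)
    if not keep.any():
        raise ModelError("degenerate cohort: all shapes identical")
    lam, Vt = lam[keep], Vt[keep]
    coeffs = U[:, keep] * s[keep]  # (S, k) training coefficients
    # deterministic sign: largest-magnitude training coefficient positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(coeffs[:, i]))
        if coeffs[j, i] < 0:
            Vt[i] = -Vt[i]
            coeffs[:, i] = -coeffs[:, i]
    model = ShapeModel(mean=mean, modes=Vt, eigenvalues=lam, n_shapes=S,
                       template_id=tid)
    model.validate()
    return model


def project(model: ShapeModel, shape: CorrespondedShape | np.ndarray,
            ) -> np.ndarray:
    """Mode coefficients (mm units) of a shape in the model's basis."""
    x = shape.flat if isinstance(shape, CorrespondedShape) else \
        np.asarray(shape).reshape(-1)
    return model.modes @ (x - model.mean)


def synthesize(model: ShapeModel, weights) -> CorrespondedShape:
    """Shape at SD-unit mode weights: M̄ + Σ w_i √λ_i φ_i.

    ``weights`` is a mapping {mode index: weight} or a dense array.  Weights
    beyond ±3 SD get a warning (the study convention explores ±3 SD).
    """
    w = np.zeros(model.n_modes)
    if isinstance(weights, dict):
        for i, wi in weights.items():
            if not 0 <= i < model.n_modes:
                raise ModelError(f"mode index {i} out of range "
                                 f"(model has {model.n_modes} modes)")
            w[i] = wi
    else:
        arr = np.asarray(weights, dtype=np.float64)
        if len(arr) > model.n_modes:
            raise ModelError("more weights than model modes")
        w[:len(arr)] = arr
    if np.any(np.abs(w) > 3.0 + 1e-12):
        warnings.warn("mode weights beyond +/-3 SD extrapolate outside the "
                      "study convention")
    x = model.mean + (w * np.sqrt(model.eigenvalues)) @ model.modes
    return CorrespondedShape(points=x.reshape(-1, 3),
                             template_id=model.template_id,
                             projection_distance=np.zeros(model.n_points))


def reconstruct(model: ShapeModel, shape: CorrespondedShape | np.ndarray,
                ) -> np.ndarray:
    """Project onto all modes and re-synthesize (exact for training shapes)."""
    b = project(model, shape)
    return (model.mean + b @ model.modes).reshape(-1, 3)


def variance_report(model: ShapeModel, k: int | None = None) -> dict:
    """Per-mode and cumulative variance percentages (1 decimal)."""
    if k is None:
        k = model.n_modes
    if not 1 <= k <= model.n_modes:
        raise ModelError(f"k={k} outside [1, {model.n_modes}]")
    frac = model.variance_fractions * 100.0
    per_mode = np.round(frac[:k], 1)
    cumulative = np.round(np.cumsum(frac)[:k], 1)
    return {"per_mode_percent": per_mode, "cumulative_percent": cumulative}


def deviation_map(model: ShapeModel, shape: CorrespondedShape,
                  template_faces: np.ndarray) -> np.ndarray:
    """Signed per-point deviation (mm) of a shape from the reference M̄,
    projected on the mean shape's outward vertex normals (positive =
    outward)."""
    import trimesh
    mean_pts = model.mean.reshape(-1, 3)
    if shape.points.shape != mean_pts.shape:
        raise ModelError("shape is not in this model's correspondence")
    mean_mesh = trimesh.Trimesh(vertices=mean_pts, faces=template_faces,
                                process=False)
    normals = np.asarray(mean_mesh.vertex_normals)
    return np.einsum("ij,ij->i", shape.points - mean_pts, normals)
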