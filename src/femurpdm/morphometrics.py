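"""Morphometric features of femoral, canal and reconstructed meshes.

All measurement functions assume the mesh is expressed in the anatomical
frame (x medial, y anterior, z proximal); pass ``frame`` to transform on the
fly otherwise.  Angles are degrees, offsets cm, volumes cm^3.

Feature definitions
-------------------
* femoral version (NFV/PFV): axial-plane angle of the neck axis against the
  posterior condylar axis (x̂), anteversion positive.
* varus/valgus: coronal-plane lean of the shaft axis from ẑ, valgus (medial
  lean of the proximal end) positive.
* neck-shaft angle (NSA): 3D angle between the neck and shaft axes, reported
  with the conventional obtuse (~125 deg) opening.
* VFO / HFO: vertical offset of the head center above the lesser-trochanter
  apex, and perpendicular distance of the head center from the shaft axis.
* neck-cut / intramedullary version: head-less surrogate for axial rotation,
  measured on the planar osteotomy face.  The default surrogate is the axial
  azimuth of the cut-face normal (exactly the version for a cut perpendicular
  to the neck axis); ``method="chord"`` gives the medial–lateral extreme-point
  chord, meaningful only for elongated (oblique) cut faces.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import trimesh

from .mesh import MeshError, OsteotomyPlane, fit_sphere


class MeasurementError(ValueError):
    pass


@dataclass
class AxisEstimate:
    point: np.ndarray       # a point on the axis, mm
    direction: np.ndarray   # unit direction
    inliers: int
    rms_residual: float     # mm


@dataclass
class MorphometricProfile:
    """Named feature values for one shape; ``None`` marks a feature that is
    not applicable to the model kind (printed as '----' in report tables)."""

    nfv_or_pfv: float | None = None        # deg
    varus_valgus: float | None = None      # deg, valgus positive
    neck_shaft_angle: float | None = None  # deg
    size: float | None = None              # cm^3
    head_radius: float | None = None       # cm
    vfo: float | None = None               # cm
    hfo: float | None = None               # cm
    neck_cut_version: float | None = None  # deg (models 2-3 surrogate)

    def available(self, name: str) -> bool:
        return getattr(self, name) is not None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def feature_names() -> list[str]:
        return [f.name for f in fields(MorphometricProfile)]


def _fold_azimuth(deg: float) -> float:
    """Fold an axial-plane angle of an undirected line into (-90, 90]."""
    a = (deg + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def _maybe_transform(mesh: trimesh.Trimesh, frame) -> trimesh.Trimesh:
    if frame is None:
        return mesh
    from .anatomy import express_in_frame  # local import to avoid cycle
    verts = frame.to_frame(mesh.vertices)
    return trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------

def shaft_axis(mesh: trimesh.Trimesh, frame=None,
               slab_thickness: float = 5.0,
               distal_fraction: float = 0.45) -> AxisEstimate:
    """Line fit through centroids of transverse slabs of the distal shaft.

    Slabs cover the distal ``distal_fraction`` of the z-extent (skipping a
    thin band at the capped cut face), which keeps them below the lesser
    trochanter on proximal-femur meshes.  A second pass drops slabs whose
    centroid is an outlier of the first-pass line (cut-face or flare
    contamination).
    """
    mesh = _maybe_transform(mesh, frame)
    z = mesh.vertices[:, 2]
    span = z.max() - z.min()
    if span < 60.0:
        raise MeasurementError(f"mesh spans only {span:.1f} mm along z; "
                               "need >= 60 for a shaft axis")
    z_lo = z.min() + slab_thickness
    z_hi = z.min() + distal_fraction * span
    centroids = []
    lo = z_lo
    while lo + slab_thickness <= z_hi + 1e-9:
        sel = (z >= lo) & (z < lo + slab_thickness)
        if np.count_nonzero(sel) >= 8:
            centroids.append(mesh.vertices[sel].mean(axis=0))
        lo += slab_thickness
    if len(centroids) < 4:
        raise MeasurementError(f"only {len(centroids)} usable slabs (< 4)")
    c = np.array(centroids)

    def _fit(c):
        mean = c.mean(axis=0)
        _, _, vt = np.linalg.svd(c - mean)
        d = vt[0]
        if d[2] < 0:
            d = -d  # orient proximally
        resid = np.linalg.norm((c - mean) - ((c - mean) @ d)[:, None] * d,
                               axis=1)
        return mean, d, resid

    mean, d, resid = _fit(c)
    keep = resid <= max(2.0 * np.median(resid), 0.2)
    if keep.sum() >= 4 and not keep.all():
        c = c[keep]
        mean, d, resid = _fit(c)
    return AxisEstimate(point=mean, direction=d, inliers=len(c),
                        rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def _section_loops(mesh: trimesh.Trimesh, origin, normal):
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    loops = []
    for poly in sec.discrete:
        pts = np.asarray(poly)
        seg = np.diff(pts, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        if lens.sum() < 1e-9:
            continue
        mids = 0.5 * (pts[:-1] + pts[1:])
        centroid = (mids * lens[:, None]).sum(axis=0) / lens.sum()
        loops.append((centroid, float(lens.sum())))
    return loops


#: plausible femoral/prosthetic head radius band (mm); a converged fit
#: outside it (e.g. the small capsule dome of a canal mesh) is not a head
HEAD_RADIUS_RANGE = (12.0, 40.0)


def fit_head_sphere(mesh: trimesh.Trimesh, head_seed: np.ndarray,
                    band: float = 1.2) -> tuple[np.ndarray, float, float]:
    """Iteratively reweighted sphere fit of the femoral head.

    Starting from the seed, vertices within ``band`` x the current radius of
    the current center are refit until the center converges.  Raises
    "no spherical head" when the residual exceeds 15% of the radius or the
    converged radius is anatomically implausible (e.g. on canal meshes or
    arbitrary solids).
    """
    verts = np.asarray(mesh.vertices)
    center = np.asarray(head_seed, dtype=np.float64)
    radius = 25.0
    rms = np.inf
    for _ in range(15):
        sel = np.linalg.norm(verts - center, axis=1) < band * radius
        if np.count_nonzero(sel) < 10:
            raise MeasurementError("no spherical head near the seed point")
        try:
            c_new, r_new, rms = fit_sphere(verts[sel])
        except MeshError as exc:
            raise MeasurementError(f"no spherical head: {exc}") from exc
        shift = np.linalg.norm(c_new - center)
        center, radius = c_new, r_new
        if shift < 1e-8:
            break
    # trim the neck-junction bulge (one-sided positive residuals) and refit
    for _ in range(3):
        sel = np.linalg.norm(verts - center, axis=1) < band * radius
        pts = verts[sel]
        resid = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
        keep = resid < max(2.5 * resid.std(), 0.05)
        if keep.sum() < 10 or keep.all():
            break
        try:
            center, radius, rms = fit_sphere(pts[keep])
        except MeshError as exc:
            raise MeasurementError(f"no spherical head: {exc}") from exc
    if not np.isfinite(radius) or radius <= 0 or rms > 0.15 * radius:
        raise MeasurementError(
            f"no spherical head (fit rms {rms:.2f} mm vs radius {radius:.1f})")
    if not HEAD_RADIUS_RANGE[0] <= radius <= HEAD_RADIUS_RANGE[1]:
        raise MeasurementError(
            f"no spherical head (converged radius {radius:.1f} mm outside "
            f"the plausible band {HEAD_RADIUS_RANGE})")
    return center, float(radius), float(rms)


def fit_sphere_to_indexed(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Robust sphere fit to a fixed point set (one outlier-trim pass).

    Used for corresponded/synthesized shapes where the head vertex set is
    known by index: keeping the selection fixed across shapes removes the
    selection jitter a distance-based band would introduce.
    """
    center, radius, _ = fit_sphere(points)
    resid = np.abs(np.linalg.norm(points - center, axis=1) - radius)
    keep = resid < max(2.5 * resid.std(), 0.05)
    if 10 <= keep.sum() < len(points):
        center, radius, _ = fit_sphere(points[keep])
    return center, float(radius)


def shaft_slab_groups(points: np.ndarray, slab_thickness: float = 5.0,
                      distal_fraction: float = 0.45) -> list[np.ndarray]:
    """Vertex index groups of the distal transverse slabs, for callers who
    want to freeze the slab membership across corresponded shapes.

    Slabs whose ring center is an outlier of the axis through all ring
    centers (e.g. slabs contaminated by the lesser-trochanter bump) are
    dropped before freezing, mirroring the rejection the direct slab-based
    axis fit applies.
    """
    z = points[:, 2]
    span = z.max() - z.min()
    groups = []
    lo = z.min() + slab_thickness
    z_hi = z.min() + distal_fraction * span
    while lo + slab_thickness <= z_hi + 1e-9:
        sel = np.nonzero((z >= lo) & (z < lo + slab_thickness))[0]
        if len(sel) >= 8:
            groups.append(sel)
        lo += slab_thickness
    if len(groups) > 4:
        centers = np.array([np.append(_circle_center_2d(points[g][:, :2]),
                                      points[g][:, 2].mean())
                            for g in groups])
        mean = centers.mean(axis=0)
        _, _, vt = np.linalg.svd(centers - mean)
        d = vt[0]
        resid = np.linalg.norm((centers - mean)
                               - ((centers - mean) @ d)[:, None] * d, axis=1)
        keep = resid <= max(2.0 * np.median(resid), 0.2)
        if keep.sum() >= 4:
            groups = [g for g, k in zip(groups, keep) if k]
    return groups


def _circle_center_2d(xy: np.ndarray) -> np.ndarray:
    """Algebraic least-squares circle center (density independent)."""
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    rhs = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return sol[:2]


def shaft_axis_from_groups(points: np.ndarray,
                           groups: list[np.ndarray]) -> AxisEstimate:
    """Shaft axis through the per-slab ring centers of frozen index groups.

    Each slab's center is a least-squares circle fit in the transverse
    plane rather than a vertex centroid: the circle center is insensitive
    to azimuthally nonuniform vertex density, which corresponded points can
    develop by sliding tangentially along the shaft.
    """
    if len(groups) < 4:
        raise MeasurementError(f"only {len(groups)} slab groups (< 4)")
    c = []
    for g in groups:
        pts = points[g]
        cx, cy = _circle_center_2d(pts[:, :2])
        c.append([cx, cy, pts[:, 2].mean()])
    c = np.array(c)
    mean = c.mean(axis=0)
    _, _, vt = np.linalg.svd(c - mean)
    d = vt[0]
    if d[2] < 0:
        d = -d
    resid = np.linalg.norm((c - mean) - ((c - mean) @ d)[:, None] * d,
                           axis=1)
    return AxisEstimate(point=mean, direction=d, inliers=len(c),
                        rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def neck_axis(mesh: trimesh.Trimesh, head_seed: np.ndarray, frame=None,
              head_fit: tuple | None = None,
              shaft: AxisEstimate | None = None,
              ) -> tuple[np.ndarray, AxisEstimate]:
    """Head center by iterative sphere fitting, then the neck axis as the line
    from the minimum-girth neck section (waist) to the head center.

    The waist search slices the mesh perpendicular to the current neck
    direction at stations between the head sphere and the trochanteric flare;
    stations whose section girth is close to the minimum define the neck tube
    and their (length-weighted) centroids fix the axis.  Two passes refine
    the initial direction guess taken from the shaft-axis geometry.
    """
    mesh = _maybe_transform(mesh, frame)
    if head_fit is not None:
        center, radius = np.asarray(head_fit[0], dtype=np.float64), \
            float(head_fit[1])
    else:
        center, radius, _ = fit_head_sphere(mesh, head_seed)
    if shaft is None:
        shaft = shaft_axis(mesh)
    # foot of the perpendicular from the head center to the shaft axis
    w = center - shaft.point
    q = shaft.point + (w @ shaft.direction) * shaft.direction
    hfo_mm = np.linalg.norm(center - q)
    if hfo_mm < 1e-6:
        raise MeasurementError("head center lies on the shaft axis: neck "
                               "direction undefined")
    # initial neck-base estimate assumes a ~125 deg neck-shaft angle
    # (cot 55 deg ~ 0.70); refined below from the measured direction
    base = q - 0.70 * hfo_mm * shaft.direction
    est = None
    for _ in range(2):
        direction = base - center
        L = np.linalg.norm(direction)
        direction /= L
        stations = []
        for s in np.linspace(0.95 * radius, L, 24):
            p = center + s * direction
            loops = _section_loops(mesh, p, direction)
            if not loops:
                continue
            centroid, perim = min(loops,
                                  key=lambda cp: np.linalg.norm(cp[0] - p))
            if np.linalg.norm(centroid - p) > 0.6 * radius:
                continue  # nearest loop is not the neck tube
            stations.append((centroid, perim, s))
        if len(stations) < 3:
            raise MeasurementError("could not section the femoral neck")
        perims = np.array([s[1] for s in stations])
        waist_perim = perims.min()
        # the free neck tube has near-constant girth; a tight band rejects
        # sections contaminated by the head-neck or neck-shaft blends, whose
        # centroids are pulled smoothly off-axis
        keep = perims <= 1.02 * waist_perim
        pts = np.array([s[0] for s in stations])[keep]
        waist = np.array(stations[int(np.argmin(perims))][0])
        # head center (sub-0.2 mm accurate) to the clean-tube centroid mean:
        # ~30 mm lever keeps the direction error well under half a degree
        d = center - pts.mean(axis=0)
        d /= np.linalg.norm(d)
        cloud = np.vstack([pts, center])
        mean = cloud.mean(axis=0)
        resid = np.linalg.norm((cloud - mean)
                               - ((cloud - mean) @ d)[:, None] * d, axis=1)
        est = AxisEstimate(point=waist, direction=d, inliers=int(keep.sum()),
                           rms_residual=float(np.sqrt(np.mean(resid ** 2))))
        # refine the base estimate using the measured neck-shaft angle
        eta = np.arccos(np.clip(d @ shaft.direction, -1, 1))
        cot = 1.0 / max(np.tan(eta), 0.2) if eta < np.pi / 2 else \
            -1.0 / max(np.tan(np.pi - eta), 0.2)
        base = q - cot * hfo_mm * shaft.direction
    return center, est


def head_radius_cm(mesh: trimesh.Trimesh, head_seed: np.ndarray,
                   frame=None) -> float:
    mesh = _maybe_transform(mesh, frame)
    _, radius, _ = fit_head_sphere(mesh, head_seed, band=1.1)
    return radius / 10.0


# ---------------------------------------------------------------------------
# angle features
# ---------------------------------------------------------------------------

def femoral_version(mesh: trimesh.Trimesh, head_seed: np.ndarray,
                    frame=None) -> float:
    """Axial-plane angle of the neck axis vs the posterior condylar axis,
    anteversion positive, in (-90, 90]."""
    _, est = neck_axis(mesh, head_seed, frame)
    u = est.direction
    return _fold_azimuth(np.degrees(np.arctan2(u[1], u[0])))


def varus_valgus(mesh: trimesh.Trimesh, frame=None) -> float:
    """Coronal-plane angle of the shaft axis from vertical, valgus positive."""
    est = shaft_axis(mesh, frame)
    d = est.direction
    return float(np.degrees(np.arctan2(d[0], d[2])))


def neck_shaft_angle(mesh: trimesh.Trimesh, head_seed: np.ndarray,
                     frame=None) -> float:
    """3D neck-shaft angle with the conventional obtuse opening, in (0, 180)."""
    _, neck = neck_axis(mesh, head_seed, frame)
    shaft = shaft_axis(mesh, frame)
    cosang = np.clip(neck.direction @ shaft.direction, -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))  # waist->head vs proximal shaft
    nsa = 180.0 - theta
    if nsa >= 179.5:
        raise MeasurementError("neck collinear with shaft (degenerate NSA)")
    return float(nsa)


def offsets(mesh: trimesh.Trimesh, head_seed: np.ndarray,
            lt_apex: np.ndarray | None, frame=None,
            ) -> tuple[float | None, float]:
    """(VFO, HFO) in cm; VFO is None when the LT apex landmark is missing.

    Only the head center and shaft axis are needed, so this stays defined
    even when the head sits on the shaft axis (HFO = 0)."""
    mesh_f = _maybe_transform(mesh, frame)
    center, _, _ = fit_head_sphere(mesh_f, head_seed)
    shaft = shaft_axis(mesh_f)
    w = center - shaft.point
    hfo = np.linalg.norm(w - (w @ shaft.direction) * shaft.direction) / 10.0
    vfo = None
    if lt_apex is not None:
        vfo = float((center[2] - np.asarray(lt_apex)[2]) / 10.0)
    return vfo, float(hfo)


# ---------------------------------------------------------------------------
# osteotomy-face surrogate version
# ---------------------------------------------------------------------------

def cut_face_vertex_indices(mesh: trimesh.Trimesh, plane: OsteotomyPlane,
                            angle_tol_deg: float = 5.0,
                            dist_tol: float = 1.0) -> np.ndarray:
    """Vertex indices of the planar capped cut face matching ``plane``."""
    fn = mesh.face_normals
    align = np.abs(fn @ plane.normal) > np.cos(np.radians(angle_tol_deg))
    d = np.abs(plane.signed_distance(mesh.vertices))
    close = d < dist_tol
    face_ok = align & close[mesh.faces].all(axis=1)
    if not face_ok.any():
        raise MeasurementError("no planar cut face found matching the plane")
    return np.unique(mesh.faces[face_ok])


def version_from_cut_points(points: np.ndarray,
                            method: str = "normal") -> float:
    """Surrogate axial-rotation measure from the cut-face point cluster.

    ``normal``: azimuth of the best-fit plane normal of the cluster (equals
    the femoral version for a neck-perpendicular osteotomy).  ``chord``:
    azimuth of the line between the most medial (max x) and most lateral
    (min x) cluster points.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise MeasurementError("cut face cluster too small")
    if method == "normal":
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c)
        n = vt[2]
        if np.hypot(n[0], n[1]) < 1e-9:
            raise MeasurementError("cut face normal has no axial component")
        return _fold_azimuth(np.degrees(np.arctan2(n[1], n[0])))
    if method == "chord":
        p_med = pts[np.argmax(pts[:, 0])]
        p_lat = pts[np.argmin(pts[:, 0])]
        u = p_med - p_lat
        if np.hypot(u[0], u[1]) < 1e-9:
            raise MeasurementError("degenerate medial-lateral chord")
        return _fold_azimuth(np.degrees(np.arctan2(u[1], u[0])))
    raise ValueError(f"unknown method {method!r}")


def neck_cut_version(mesh: trimesh.Trimesh, plane: OsteotomyPlane,
                     frame=None, method: str = "normal") -> float:
    """Surrogate version from the planar osteotomy face of a head-less model."""
    mesh = _maybe_transform(mesh, frame)
    idx = cut_face_vertex_indices(mesh, plane)
    return version_from_cut_points(mesh.vertices[idx], method=method)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

MODEL_KINDS = ("native", "post_osteotomy", "canal", "reconstructed")

#: features measured per model kind; everything else is flagged unavailable
FEATURES_BY_KIND = {
    "native": ("nfv_or_pfv", "varus_valgus", "neck_shaft_angle", "size",
               "head_radius", "vfo", "hfo"),
    "post_osteotomy": ("neck_cut_version", "varus_valgus", "size"),
    "canal": ("neck_cut_version", "varus_valgus", "size"),
    "reconstructed": ("nfv_or_pfv", "varus_valgus", "neck_shaft_angle",
                      "size", "vfo", "hfo"),
}


def profile(mesh: trimesh.Trimesh, landmarks=None, model_kind: str = "native",
            cut_plane: OsteotomyPlane | None = None, frame=None,
            cut_face_indices: np.ndarray | None = None,
            head_fit: tuple | None = None,
            shaft_fit: AxisEstimate | None = None,
            ) -> MorphometricProfile:
    """Measure the features applicable to ``model_kind`` on one mesh.

    ``cut_face_indices`` lets callers who track point correspondence (e.g.
    on PCA-synthesized shapes, where the averaged cut face is only nearly
    planar) bypass the strict planar-face detection; ``head_fit`` similarly
    supplies a pre-fitted (center, radius) of the head sphere computed from
    a tracked vertex set.
    """
    from .mesh import mesh_volume
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    mesh = _maybe_transform(mesh, frame)
    wanted = FEATURES_BY_KIND[model_kind]
    out = MorphometricProfile()
    if "nfv_or_pfv" in wanted:
        seed = landmarks["head_seed"] if landmarks is not None else None
        if seed is None and head_fit is None:
            raise MeasurementError(f"{model_kind} profile needs a head seed")
        center, est = neck_axis(mesh, seed, head_fit=head_fit,
                                shaft=shaft_fit)
        u = est.direction
        out.nfv_or_pfv = _fold_azimuth(np.degrees(np.arctan2(u[1], u[0])))
        shaft = shaft_fit if shaft_fit is not None else shaft_axis(mesh)
        theta = np.degrees(np.arccos(np.clip(u @ shaft.direction, -1, 1)))
        out.neck_shaft_angle = 180.0 - theta
        w = center - shaft.point
        out.hfo = float(np.linalg.norm(
            w - (w @ shaft.direction) * shaft.direction) / 10.0)
        if "vfo" in wanted and landmarks is not None \
                and "lt_apex" in landmarks.points:
            out.vfo = float((center[2] - landmarks["lt_apex"][2]) / 10.0)
        if "head_radius" in wanted:
            out.head_radius = head_fit[1] / 10.0 if head_fit is not None \
                else head_radius_cm(mesh, seed)
    out.size = mesh_volume(mesh)
    if shaft_fit is not None:
        d = shaft_fit.direction
        out.varus_valgus = float(np.degrees(np.arctan2(d[0], d[2])))
    else:
        out.varus_valgus = varus_valgus(mesh)
    if "neck_cut_version" in wanted:
        if cut_face_indices is not None:
            out.neck_cut_version = version_from_cut_points(
                np.asarray(mesh.vertices)[cut_face_indices])
        elif cut_plane is not None:
            out.neck_cut_version = neck_cut_version(mesh, cut_plane)
        else:
            raise MeasurementError(
                f"{model_kind} profile needs the osteotomy plane or a cut-face "
                "index set")
    return out
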