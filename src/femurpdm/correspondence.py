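"""Dense point correspondence across an aligned cohort.

Each cohort surface is re-expressed as an ordered set of points with
index-wise anatomical correspondence to a common template: template vertex i
is shot along its outward normal (both directions) onto the target surface,
the displacement field is Laplacian-smoothed on the template graph to keep
neighbouring points coherent, and the projection is iterated, ending on the
target surface.  The resulting S x 3N data matrix is the input to the PCA
shape model.

The template itself is an isotropic remesh (voxel + isosurface + Taubin
smoothing) of the cohort member nearest the cohort's bounding-box center.
When matched landmark arrays are available, a Gaussian radial-basis warp of
the landmarks carries the template onto each target first, so the
correspondence follows anatomy (e.g. femoral torsion) rather than the
nearest geometry.  Normal shooting is deliberately simple and auditable;
the engine is behind a single function so an alternative correspondence
scheme can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .mesh import is_closed, occupancy_to_mesh, smooth as taubin_smooth, voxelize


class CorrespondenceError(ValueError):
    pass


@dataclass
class Template:
    """Common reference discretization: a closed mesh with >= 500 vertices."""

    mesh: trimesh.Trimesh
    template_id: str = "template"

    def __post_init__(self) -> None:
        if len(self.mesh.vertices) < 500:
            raise CorrespondenceError(
                f"template has {len(self.mesh.vertices)} vertices (< 500)")
        if not is_closed(self.mesh):
            raise CorrespondenceError("template mesh must be closed")

    @property
    def n_points(self) -> int:
        return len(self.mesh.vertices)


@dataclass
class CorrespondedShape:
    """Ordered point set in the template's vertex order."""

    points: np.ndarray           # (N, 3) mm
    template_id: str
    projection_distance: np.ndarray  # (N,) mm

    @property
    def flat(self) -> np.ndarray:
        return self.points.reshape(-1)

    @property
    def max_projection_distance(self) -> float:
        return float(self.projection_distance.max())

    @property
    def mean_projection_distance(self) -> float:
        return float(self.projection_distance.mean())


def remesh_isotropic(mesh: trimesh.Trimesh, n_points: int,
                     max_iter: int = 5) -> trimesh.Trimesh:
    """Resample a closed surface to ~``n_points`` near-uniform vertices by
    voxelizing, isosurfacing and lightly smoothing; the voxel pitch is
    calibrated iteratively to land within 10% of the request."""
    area = float(mesh.area)
    pitch = float(np.sqrt(2.0 * area / n_points))
    out = None
    for _ in range(max_iter):
        grid = voxelize(mesh, pitch)
        out = occupancy_to_mesh(grid, smooth_sigma=1.0)
        if out is None:
            pitch *= 0.7
            continue
        out = taubin_smooth(out, iterations=5)
        ratio = len(out.vertices) / n_points
        if 0.9 <= ratio <= 1.1:
            break
        pitch *= np.sqrt(ratio)
    if out is None:
        raise CorrespondenceError("remeshing produced no surface")
    return out


def make_template(cohort: list[trimesh.Trimesh], n_points: int = 2000,
                  ) -> Template:
    """Template = isotropic remesh of the member nearest the cohort's
    vertexwise bounding-box center."""
    if not cohort:
        raise CorrespondenceError("empty cohort")
    if n_points < 500:
        raise CorrespondenceError(f"n_points={n_points} below the minimum 500")
    all_lo = np.min([m.bounds[0] for m in cohort], axis=0)
    all_hi = np.max([m.bounds[1] for m in cohort], axis=0)
    center = 0.5 * (all_lo + all_hi)
    dists = [np.linalg.norm(0.5 * (m.bounds[0] + m.bounds[1]) - center)
             for m in cohort]
    pick = int(np.argmin(dists))
    remeshed = remesh_isotropic(cohort[pick], n_points)
    return Template(mesh=remeshed, template_id=f"member_{pick}")


# ---------------------------------------------------------------------------
# normal shooting
# ---------------------------------------------------------------------------

class _TargetIndex:
    """KD-tree-accelerated ray and nearest-point queries against one mesh."""

    def __init__(self, target: trimesh.Trimesh):
        self.tri = np.asarray(target.triangles)
        self.cent = self.tri.mean(axis=1)
        tri_r = np.linalg.norm(self.tri - self.cent[:, None, :],
                               axis=2).max(axis=1)
        # oversized triangles (e.g. the distal cap fan) would blow up the
        # query radius; keep them out of the tree and test them against
        # every ray instead
        cutoff = max(4.0 * np.median(tri_r), 1e-6)
        self.small = np.nonzero(tri_r <= cutoff)[0]
        self.big = np.nonzero(tri_r > cutoff)[0]
        self.small_r = float(tri_r[self.small].max()) if len(self.small) else 0.0
        self.tree = cKDTree(self.cent[self.small])

    def _pairs(self, points: np.ndarray, radius: float):
        lists = self.tree.query_ball_point(points, r=radius + self.small_r)
        counts = np.fromiter((len(c) for c in lists), dtype=np.int64,
                             count=len(lists))
        pi = np.repeat(np.arange(len(points)), counts)
        ti = self.small[np.fromiter((t for c in lists for t in c),
                                    dtype=np.int64, count=int(counts.sum()))]
        if len(self.big):
            pi_b = np.repeat(np.arange(len(points)), len(self.big))
            ti_b = np.tile(self.big, len(points))
            pi = np.concatenate([pi, pi_b])
            ti = np.concatenate([ti, ti_b])
        return pi, ti

    def raycast(self, points: np.ndarray, dirs: np.ndarray, radius: float,
                ) -> tuple[np.ndarray, np.ndarray]:
        """Bidirectional Moller-Trumbore: smallest-|t| hit per ray within
        ``radius``, NaN where the ray misses every candidate triangle."""
        t_best = np.full(len(points), np.nan)
        hits = np.full((len(points), 3), np.nan)
        pi, ti = self._pairs(points, radius)
        if len(pi) == 0:
            return hits, t_best
        a, b, c = self.tri[ti, 0], self.tri[ti, 1], self.tri[ti, 2]
        o, d = points[pi], dirs[pi]
        e1, e2 = b - a, c - a
        h = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - a
        u = np.einsum("ij,ij->i", s, h) * inv
        q = np.cross(s, e1)
        v = np.einsum("ij,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        eps = 1e-9
        valid = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) \
            & (np.abs(t) <= radius)
        if not valid.any():
            return hits, t_best
        pv, tv = pi[valid], t[valid]
        order = np.lexsort((np.abs(tv), pv))
        first = np.unique(pv[order], return_index=True)[1]
        idx = order[first]
        t_best[pv[idx]] = tv[idx]
        got = ~np.isnan(t_best)
        hits[got] = points[got] + t_best[got, None] * dirs[got]
        return hits, t_best

    def closest_point(self, points: np.ndarray, k: int = 32,
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Exact nearest point on the surface among the k nearest-centroid
        candidate triangles per query point."""
        k = min(k, len(self.small))
        _, cand = self.tree.query(points, k=k)
        cand = self.small[np.atleast_2d(cand)]
        if len(self.big):
            cand = np.column_stack(
                [cand, np.tile(self.big, (len(points), 1))])
        pi = np.repeat(np.arange(len(points)), cand.shape[1])
        ti = cand.ravel()
        cp = _closest_point_on_triangles(points[pi], self.tri[ti])
        d = np.linalg.norm(cp - points[pi], axis=1)
        order = np.lexsort((d, pi))
        first = np.unique(pi[order], return_index=True)[1]
        idx = order[first]
        return cp[idx], d[idx]


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point (Eberly regions)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)
    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def setmask(mask, val):
        m = mask & ~done
        out[m] = val[m]
        done[m] = True

    setmask((d1 <= 0) & (d2 <= 0), a)                       # vertex a
    setmask((d3 >= 0) & (d4 <= d3), b)                      # vertex b
    setmask((d6 >= 0) & (d5 <= d6), c)                      # vertex c
    vc = d1 * d4 - d3 * d2
    vmask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w = np.divide(d1, d1 - d3, out=np.zeros_like(d1),
                  where=(d1 - d3) != 0)
    setmask(vmask, a + w[:, None] * ab)                     # edge ab
    vb = d5 * d2 - d1 * d6
    wmask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2),
                  where=(d2 - d6) != 0)
    setmask(wmask, a + w[:, None] * ac)                     # edge ac
    va = d3 * d6 - d5 * d4
    emask = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.divide(d4 - d3, denom, out=np.zeros_like(denom),
                  where=denom != 0)
    setmask(emask, b + w[:, None] * (c - b))                # edge bc
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(denom), where=denom != 0)
    w = np.divide(vc, denom, out=np.zeros_like(denom), where=denom != 0)
    setmask(np.ones(len(p), dtype=bool),
            a + v[:, None] * ab + w[:, None] * ac)          # interior
    return out


def tps_warp(src: np.ndarray, dst: np.ndarray, reg: float = 1e-8,
             bandwidth: float = 40.0):
    """Landmark-interpolating space warp carrying ``src`` control points to
    ``dst``.

    The displacement field is a Gaussian radial-basis interpolant of the
    control displacements added to the identity.  The Gaussian kernel has
    zero gradient at each control point, so the neighbourhood of a landmark
    rides rigidly with it instead of being sheared by the long-range
    influence of distant landmarks (which the classic r-kernel thin-plate
    spline would introduce); far from all controls the warp decays to the
    identity.  The default 40 mm bandwidth matches the spatial scale of
    proximal-femoral features.  Returns a callable mapping (n, 3) points.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    k = len(src)
    if k < 4:
        raise CorrespondenceError("landmark warp needs >= 4 control points")
    pd = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    K = np.exp(-0.5 * (pd / bandwidth) ** 2)
    K += reg * np.eye(k)
    w = np.linalg.solve(K, dst - src)

    def warp(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        d = np.linalg.norm(points[:, None, :] - src[None, :, :], axis=2)
        return points + np.exp(-0.5 * (d / bandwidth) ** 2) @ w

    return warp


def _smooth_field(field: np.ndarray, edges: np.ndarray, weight: float,
                  sweeps: int = 2) -> np.ndarray:
    out = field.copy()
    n = len(field)
    for _ in range(sweeps):
        acc = np.zeros_like(out)
        cnt = np.zeros(n)
        np.add.at(acc, edges[:, 0], out[edges[:, 1]])
        np.add.at(acc, edges[:, 1], out[edges[:, 0]])
        np.add.at(cnt, edges[:, 0], 1.0)
        np.add.at(cnt, edges[:, 1], 1.0)
        mean = acc / np.maximum(cnt, 1.0)[:, None]
        out = (1.0 - weight) * out + weight * mean
    return out


def correspond(template: Template, target: trimesh.Trimesh,
               iterations: int = 3, smooth_weight: float = 0.5,
               search_radius: float = 10.0,
               max_unmatched_fraction: float = 0.05,
               source_landmarks: np.ndarray | None = None,
               target_landmarks: np.ndarray | None = None,
               ) -> CorrespondedShape:
    """Project every template vertex onto the target surface.

    When matched landmark arrays are supplied the template is first carried
    onto the target by a thin-plate-spline warp of the landmarks, so the
    correspondence follows anatomy (e.g. a rotated neck) rather than the
    nearest geometry.  Each outer iteration then shoots rays along the
    (fixed) template normals from the current point estimates and
    Laplacian-smooths the displacement field on the template graph; the
    final iteration ends with a pure projection so every corresponded point
    lies on the target surface.  Points whose ray misses within
    ``search_radius`` fall back to the nearest surface point; if more than
    ``max_unmatched_fraction`` of points have no surface within the search
    radius the correspondence fails.
    """
    base = np.asarray(template.mesh.vertices, dtype=np.float64)
    normals = np.asarray(template.mesh.vertex_normals, dtype=np.float64)
    edges = template.mesh.edges_unique
    index = _TargetIndex(target)
    if source_landmarks is not None and target_landmarks is not None:
        warp = tps_warp(source_landmarks, target_landmarks)
        start = warp(base)
    else:
        start = base.copy()
    cur = start.copy()
    proj_dist = np.zeros(len(base))
    for it in range(iterations):
        # after the first pass the points sit close to the surface, so a
        # short ray suffices and keeps the candidate sets small
        radius = search_radius if it == 0 else min(search_radius, 3.0)
        hits, t = index.raycast(cur, normals, radius)
        miss = np.isnan(t)
        if miss.any():
            closest, dist = index.closest_point(cur[miss])
            hits[miss] = closest
            t[miss] = dist
            unmatched = float(np.mean(dist > search_radius)) \
                * np.mean(miss)
            if unmatched > max_unmatched_fraction:
                raise CorrespondenceError(
                    f"{100 * unmatched:.1f}% of template points found no "
                    f"surface within {search_radius} mm")
        proj_dist = np.abs(t)
        if it < iterations - 1:
            # smooth the residual after the landmark warp, so the warp's
            # large (anatomical) displacements do not bleed into
            # neighbouring regions through the smoothing
            disp = _smooth_field(hits - start, edges, smooth_weight)
            cur = start + disp
        else:
            cur = hits
    return CorrespondedShape(points=cur, template_id=template.template_id,
                             projection_distance=proj_dist)


def mean_shape(shapes: list[CorrespondedShape]) -> CorrespondedShape:
    """Index-wise arithmetic mean: the cohort's reference geometry."""
    if not shapes:
        raise CorrespondenceError("mean of empty shape list")
    ns = {s.points.shape for s in shapes}
    if len(ns) != 1:
        raise CorrespondenceError(f"mixed point counts: {sorted(ns)}")
    pts = np.mean([s.points for s in shapes], axis=0)
    pd = np.mean([s.projection_distance for s in shapes], axis=0)
    return CorrespondedShape(points=pts, template_id=shapes[0].template_id,
                             projection_distance=pd)


def data_matrix(shapes: list[CorrespondedShape]) -> np.ndarray:
    """Stack a cohort into the S x 3N matrix consumed by the shape model."""
    if not shapes:
        return np.zeros((0, 0))
    return np.vstack([s.flat for s in shapes])
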