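"""Parametric proximal-femur generator.

Cohorts of hollow proximal femora (~15 cm once standardized) are produced with
controlled anatomical parameters — femoral version, neck-shaft angle (NSA),
varus/valgus shaft lean, head radius, overall scale, canal geometry — standing
in for patient CT segmentations.  Each specimen is built by composing a signed
distance field (shaft of revolution, neck capsule, head sphere, greater/lesser
trochanter bumps, intramedullary canal tube) and extracting isosurfaces by
marching cubes, which guarantees closed manifold output for any admissible
parameter combination.

Everything is constructed directly in the anatomical coordinate frame of a
left femur: x medial, y anterior, z proximal, with virtual posterior-condyle
landmarks emitted analytically (the meshes are proximal-only, so real condyles
are not on the surface).  Right-sided specimens are the same geometry with the
y axis negated, which is how a right femur appears when expressed in its own
condyle-based frame.

Ground truth (true head center, true morphometric profile, osteotomy plane) is
recorded for every specimen so downstream measurements can be validated by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from .anatomy import LandmarkSet
from .mesh import MeshError, OsteotomyPlane, as_mesh, weld_vertices
from .morphometrics import MorphometricProfile

#: smooth-union blending radius at neck/shaft and head/neck junctions (mm);
#: avoids non-anatomic creases that would break correspondence
BLEND_NECK = 3.0
BLEND_TROCH = 5.0
#: fixed prosthetic neck-shaft angle of the (single) stem design, degrees
STEM_NSA = 132.0
#: voxel pitch used to integrate the ground-truth solid volume (mm)
TRUTH_VOLUME_PITCH = 0.7


class ParameterError(ValueError):
    """Invalid anatomical parameters."""


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class FemurParams:
    """Anatomical parameters of one synthetic proximal femur (mm / degrees)."""

    side: str = "left"
    shaft_length: float = 175.0
    shaft_outer_radius: float = 15.0
    cortical_thickness: float = 7.0
    canal_flare_factor: float = 1.5
    neck_shaft_angle: float = 125.0
    version: float = 15.0
    varus_valgus: float = 7.0
    neck_length: float = 50.0
    neck_radius: float = 13.0
    head_radius: float = 23.0
    gt_height: float = 8.0
    lt_offset: float = 40.0
    global_scale: float = 1.0
    noise_amplitude: float = 0.0
    mesh_resolution: float = 1.0

    def validate(self) -> None:
        p = self
        if p.side not in ("left", "right"):
            raise ParameterError(f"side must be left/right, got {p.side!r}")
        if not (p.cortical_thickness < p.shaft_outer_radius):
            raise ParameterError("cortical_thickness must be < shaft_outer_radius "
                                 "(no canal would exist)")
        if not (90.0 <= p.neck_shaft_angle <= 160.0):
            raise ParameterError("neck_shaft_angle outside [90, 160] deg")
        if not (-30.0 <= p.version <= 60.0):
            raise ParameterError("version outside [-30, 60] deg")
        if not (p.head_radius > p.neck_radius):
            raise ParameterError("head_radius must exceed neck_radius")
        if p.canal_flare_factor < 1.0:
            raise ParameterError("canal_flare_factor must be >= 1")
        if p.global_scale <= 0:
            raise ParameterError("global_scale must be > 0")
        if p.noise_amplitude < 0:
            raise ParameterError("noise_amplitude must be >= 0")
        if p.mesh_resolution <= 0:
            raise ParameterError("mesh_resolution must be > 0")
        if p.mesh_resolution > p.cortical_thickness * p.global_scale / 2.0:
            raise ParameterError(
                f"mesh_resolution {p.mesh_resolution} too coarse to resolve "
                f"cortical thickness {p.cortical_thickness * p.global_scale}")

    def scaled(self) -> "FemurParams":
        """Copy with all linear dimensions multiplied by ``global_scale``."""
        s = self.global_scale
        return dataclasses.replace(
            self, shaft_length=self.shaft_length * s,
            shaft_outer_radius=self.shaft_outer_radius * s,
            cortical_thickness=self.cortical_thickness * s,
            neck_length=self.neck_length * s,
            neck_radius=self.neck_radius * s,
            head_radius=self.head_radius * s,
            gt_height=self.gt_height * s, lt_offset=self.lt_offset * s,
            global_scale=1.0)


@dataclass
class StemParams:
    """Prosthetic stem parameters (triple-taper approximation)."""

    stem_version: float = 15.0   # prosthetic femoral version, deg
    stem_length: float = 110.0   # mm below the shoulder
    neck_length: float = 38.0    # shoulder to prosthetic head center, mm
    head_radius: float = 16.0    # mm
    taper: float = 0.45          # fractional radius reduction shoulder->tip
    seated_depth: float = 6.0    # shoulder below the osteotomy level, mm

    def validate(self) -> None:
        if self.stem_length <= 0:
            raise ParameterError("stem_length must be > 0")
        if not (0.0 <= self.taper < 1.0):
            raise ParameterError("taper must be in [0, 1)")
        if self.neck_length <= 0 or self.head_radius <= 0:
            raise ParameterError("neck_length and head_radius must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually built, for parameter-recovery checks."""

    params: FemurParams
    landmarks: LandmarkSet
    profile: MorphometricProfile
    head_center: np.ndarray
    shaft_axis_point: np.ndarray
    shaft_axis_dir: np.ndarray
    neck_axis_dir: np.ndarray
    osteotomy_plane: OsteotomyPlane


# ---------------------------------------------------------------------------
# signed-distance primitives (vectorized over (n, 3) point arrays)
# ---------------------------------------------------------------------------

def _sd_sphere(p, c, r):
    return np.linalg.norm(p - c, axis=1) - r


def _sd_capsule(p, a, b, r):
    ab = b - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - a - t[:, None] * ab, axis=1) - r


def _smin(a, b, k):
    """Polynomial smooth minimum with blending radius ``k``."""
    if k <= 0:
        return np.minimum(a, b)
    h = np.clip(k - np.abs(a - b), 0.0, None) / k
    return np.minimum(a, b) - h * h * k * 0.25


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# geometry assembly
# ---------------------------------------------------------------------------

class _FemurGeometry:
    """Derived construction geometry of one (scaled, left-handed) femur."""

    def __init__(self, p: FemurParams):
        self.p = p
        vv = np.radians(p.varus_valgus)
        v = np.radians(p.version)
        eta = np.radians(180.0 - p.neck_shaft_angle)  # neck vs proximal shaft
        # proximal shaft direction: valgus = medial (+x) lean of proximal end
        self.d = np.array([np.sin(vv), 0.0, np.cos(vv)])
        self.t_base = p.shaft_length - 20.0
        self.b = self.t_base * self.d  # neck base point on the shaft axis
        # neck direction: polar angle phi from +z chosen so that the angle to
        # the shaft axis is exactly eta while the axial-plane azimuth is
        # exactly the femoral version
        A = np.cos(v) * np.sin(vv)
        B = np.cos(vv)
        R = np.hypot(A, B)
        delta = np.arctan2(A, B)
        phi = delta + np.arccos(np.clip(np.cos(eta) / R, -1.0, 1.0))
        self.n = np.array([np.sin(phi) * np.cos(v), np.sin(phi) * np.sin(v),
                           np.cos(phi)])
        self.head_center = self.b + p.neck_length * self.n
        # greater trochanter: lateral bump.  Version is a torsion of the neck
        # alone; the trochanters keep their azimuth regardless of version.
        u_lat = np.array([-1.0, 0.0, 0.0])
        self.gt_radius = 10.0 * p.shaft_outer_radius / 15.0
        self.gt_center = ((self.t_base + p.gt_height) * self.d
                          + (p.shaft_outer_radius + 2.0) * u_lat)
        self.gt_tip = self.gt_center + np.array([0.0, 0.0, self.gt_radius])
        # lesser trochanter: posteromedial bump lt_offset below the neck base
        a_lt = -np.radians(40.0)
        u_lt = np.array([np.cos(a_lt), np.sin(a_lt), 0.0])
        self.lt_radius = 7.0 * p.shaft_outer_radius / 15.0
        self.lt_center = ((self.t_base - p.lt_offset) * self.d
                          + p.shaft_outer_radius * u_lt)
        self.lt_apex = self.lt_center + self.lt_radius * u_lt
        # canal: straight diaphyseal tube funnelling into the neck direction
        self.canal_r0 = p.shaft_outer_radius - p.cortical_thickness
        self.canal_neck_r = min(9.0 * p.shaft_outer_radius / 15.0,
                                p.neck_radius - 3.5)
        self.canal_neck_top = self.b + 18.0 * self.n
        # default osteotomy plane: perpendicular to the neck axis, 8 mm up the
        # neck from its base; normal points distally (retained side)
        self.osteotomy_plane = OsteotomyPlane(point=self.b + 8.0 * self.n,
                                              normal=-self.n)

    # -- fields ------------------------------------------------------------
    def _shaft_radial(self, pts):
        t = pts @ self.d
        radial = np.linalg.norm(pts - t[:, None] * self.d, axis=1)
        return t, radial

    def sd_bone(self, pts: np.ndarray) -> np.ndarray:
        p = self.p
        t, radial = self._shaft_radial(pts)
        top = self.t_base + 6.0
        # capsule of revolution along the shaft axis
        tt = np.clip(t, -30.0, top)
        axis_pt = tt[:, None] * self.d
        sd = np.linalg.norm(pts - axis_pt, axis=1) - p.shaft_outer_radius
        sd = _smin(sd, _sd_capsule(pts, self.b, self.head_center,
                                   p.neck_radius), BLEND_NECK)
        sd = _smin(sd, _sd_sphere(pts, self.head_center, p.head_radius),
                   BLEND_NECK)
        sd = _smin(sd, _sd_sphere(pts, self.gt_center, self.gt_radius),
                   BLEND_TROCH)
        sd = _smin(sd, _sd_sphere(pts, self.lt_center, self.lt_radius),
                   BLEND_TROCH)
        return sd

    def canal_radius(self, t: np.ndarray) -> np.ndarray:
        """Diaphyseal canal radius as a function of axial station."""
        p = self.p
        s = _smoothstep((t - (self.t_base - 60.0)) / 50.0)
        return self.canal_r0 * (1.0 + (p.canal_flare_factor - 1.0) * s)

    def sd_canal(self, pts: np.ndarray) -> np.ndarray:
        t, radial = self._shaft_radial(pts)
        sd_tube = radial - self.canal_radius(t)
        sd_tube = np.maximum(sd_tube, t - (self.t_base - 5.0))
        sd_tube = np.maximum(sd_tube, -30.0 - t)
        sd_neck = _sd_capsule(pts, self.b - 25.0 * self.n,
                              self.canal_neck_top, self.canal_neck_r)
        return _smin(sd_tube, sd_neck, 6.0)

    def sd_outer(self, pts: np.ndarray) -> np.ndarray:
        """Outer cortex solid: bone clipped to the distal face z >= 0."""
        return np.maximum(self.sd_bone(pts), -pts[:, 2])

    def sd_canal_solid(self, pts: np.ndarray) -> np.ndarray:
        return np.maximum(self.sd_canal(pts), -pts[:, 2])

    def bounds(self) -> np.ndarray:
        pad = 8.0
        pts = np.vstack([
            np.zeros(3), self.b, self.head_center, self.gt_center,
            self.lt_center, self.t_base * self.d + 6.0 * self.d,
        ])
        r = max(self.p.shaft_outer_radius + 4, self.p.head_radius,
                self.gt_radius + 4)
        lo = pts.min(axis=0) - r - pad
        hi = pts.max(axis=0) + r + pad
        lo[2] = -4.0
        return np.array([lo, hi])


def _marching(sd_fn, bounds: np.ndarray, pitch: float) -> trimesh.Trimesh:
    """Sample a signed-distance field on a grid and extract the 0-isosurface."""
    lo, hi = bounds
    nx, ny, nz = (np.ceil((hi - lo) / pitch).astype(int) + 1)
    xs = lo[0] + np.arange(nx) * pitch
    ys = lo[1] + np.arange(ny) * pitch
    zs = lo[2] + np.arange(nz) * pitch
    vol = np.empty((nx, ny, nz), dtype=np.float32)
    # evaluate in x-slabs to bound peak memory
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    for i, x in enumerate(xs):
        pts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
        vol[i] = sd_fn(pts).reshape(ny, nz).astype(np.float32)
    if vol.min() >= 0:
        raise MeshError("isosurface extraction found no interior")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0)
    verts = verts * pitch + lo
    mesh = weld_vertices(as_mesh(verts, faces), 1e-9)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _occupancy_volume(sd_fn, bounds: np.ndarray, pitch: float) -> float:
    """Voxel-count volume of ``sd < 0`` in cm^3 (ground-truth integrator)."""
    lo, hi = bounds
    nx, ny, nz = (np.ceil((hi - lo) / pitch).astype(int) + 1)
    ys = lo[1] + (np.arange(ny) + 0.5) * pitch
    zs = lo[2] + (np.arange(nz) + 0.5) * pitch
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    count = 0
    for i in range(nx):
        x = lo[0] + (i + 0.5) * pitch
        pts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
        count += int(np.count_nonzero(sd_fn(pts) < 0))
    return count * pitch ** 3 / 1000.0


def _apply_surface_noise(mesh: trimesh.Trimesh, amplitude: float,
                         rng: np.random.Generator) -> trimesh.Trimesh:
    """Seeded per-vertex displacement along normals, low-pass filtered on the
    vertex graph (emulates segmentation roughness without self-intersection)."""
    if amplitude <= 0:
        return mesh
    noise = rng.normal(0.0, amplitude, size=len(mesh.vertices))
    # two neighbour-averaging passes remove high spatial frequencies
    edges = mesh.edges_unique
    for _ in range(2):
        acc = np.zeros_like(noise)
        cnt = np.zeros_like(noise)
        np.add.at(acc, edges[:, 0], noise[edges[:, 1]])
        np.add.at(acc, edges[:, 1], noise[edges[:, 0]])
        np.add.at(cnt, edges[:, 0], 1.0)
        np.add.at(cnt, edges[:, 1], 1.0)
        noise = 0.5 * noise + 0.5 * acc / np.maximum(cnt, 1.0)
    verts = mesh.vertices + noise[:, None] * mesh.vertex_normals
    return as_mesh(verts, mesh.faces)


def _mirror_y(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    verts = mesh.vertices.copy()
    verts[:, 1] *= -1.0
    return as_mesh(verts, mesh.faces[:, ::-1])


def _landmarks(geom: _FemurGeometry, side: str) -> LandmarkSet:
    scale = geom.p.shaft_length / 175.0
    pts = {
        "condyle_posterior_medial": np.array([25.0 * scale, 0.0, -280.0 * scale]),
        "condyle_posterior_lateral": np.array([-25.0 * scale, 0.0, -280.0 * scale]),
        "intertrochanteric_crest": geom.b.copy(),
        "head_seed": geom.head_center.copy(),
        "gt_tip": geom.gt_tip.copy(),
        "lt_apex": geom.lt_apex.copy(),
    }
    return LandmarkSet(points=pts, side=side)


def _truth(geom: _FemurGeometry, p_orig: FemurParams,
           size_cm3: float) -> MorphometricProfile:
    g = geom
    hfo_mm = g.p.neck_length * np.sin(np.radians(180.0 - g.p.neck_shaft_angle))
    return MorphometricProfile(
        nfv_or_pfv=p_orig.version,
        varus_valgus=p_orig.varus_valgus,
        neck_shaft_angle=p_orig.neck_shaft_angle,
        size=size_cm3,
        head_radius=g.p.head_radius / 10.0,
        vfo=(g.head_center[2] - g.lt_apex[2]) / 10.0,
        hfo=hfo_mm / 10.0,
        neck_cut_version=p_orig.version,
    )


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_femur(params: FemurParams, rng_seed: int = 0,
                   compute_truth_volume: bool = True,
                   ) -> tuple[trimesh.Trimesh, trimesh.Trimesh, GroundTruth]:
    """Build one proximal femur: outer cortex surface, canal-wall surface and
    ground truth.  ``(params, rng_seed)`` fully determines every vertex."""
    params.validate()
    p = params.scaled()
    geom = _FemurGeometry(p)
    bounds = geom.bounds()
    pitch = p.mesh_resolution
    outer = _marching(geom.sd_outer, bounds, pitch)
    canal = _marching(geom.sd_canal_solid, bounds, pitch)
    rng = np.random.default_rng(rng_seed)
    outer = _apply_surface_noise(outer, p.noise_amplitude, rng)
    canal = _apply_surface_noise(canal, p.noise_amplitude, rng)
    size = (_occupancy_volume(geom.sd_outer, bounds, TRUTH_VOLUME_PITCH)
            if compute_truth_volume else float("nan"))
    lms = _landmarks(geom, params.side)
    plane = geom.osteotomy_plane
    head_center = geom.head_center.copy()
    d, n = geom.d.copy(), geom.n.copy()
    axis_pt = np.zeros(3)
    if params.side == "right":
        outer, canal = _mirror_y(outer), _mirror_y(canal)
        lms = lms.mirrored_y(new_side="right")
        pt, nm = plane.point.copy(), plane.normal.copy()
        pt[1] *= -1.0
        nm[1] *= -1.0
        plane = OsteotomyPlane(point=pt, normal=nm)
        head_center[1] *= -1.0
        n[1] *= -1.0
    truth = GroundTruth(params=params, landmarks=lms,
                        profile=_truth(geom, params, size),
                        head_center=head_center, shaft_axis_point=axis_pt,
                        shaft_axis_dir=d, neck_axis_dir=n,
                        osteotomy_plane=plane)
    return outer, canal, truth


def generate_reconstructed(params: FemurParams, stem: StemParams,
                           cut: OsteotomyPlane | None = None,
                           rng_seed: int = 0,
                           compute_truth_volume: bool = True,
                           ) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Osteotomized femur grouped with a seated prosthetic stem as one closed
    surface.  The recorded version truth is the stem (prosthetic) version."""
    params.validate()
    stem.validate()
    p = params.scaled()
    geom = _FemurGeometry(p)
    if cut is None:
        cut = geom.osteotomy_plane if params.side == "left" else None
    if cut is None:  # right side: mirror default plane back to build space
        base = geom.osteotomy_plane
        cut_build = base
    else:
        cut_build = cut
        if params.side == "right":
            pt, nm = cut.point.copy(), cut.normal.copy()
            pt[1] *= -1.0
            nm[1] *= -1.0
            cut_build = OsteotomyPlane(point=pt, normal=nm)
    # the cut must actually intersect the neck
    dist_to_neck = np.abs(cut_build.signed_distance(
        geom.b[None] + np.linspace(0, p.neck_length, 20)[:, None] * geom.n))
    if dist_to_neck.min() > p.neck_length:
        raise ParameterError("osteotomy plane does not intersect the neck")

    sv = np.radians(stem.stem_version)
    eta = np.radians(180.0 - STEM_NSA)
    # prosthetic neck: exact axial azimuth = stem version, polar angle set so
    # the angle to the shaft axis is exactly the stem design's NSA
    A = np.cos(sv) * geom.d[0]
    B = geom.d[2]
    phi = np.arctan2(A, B) + eta
    n_stem = np.array([np.sin(phi) * np.cos(sv), np.sin(phi) * np.sin(sv),
                       np.cos(phi)])
    # shoulder sits seated_depth below where the cut plane crosses the axis
    denom = cut_build.normal @ geom.d
    if abs(denom) < 1e-9:
        raise ParameterError("osteotomy plane is parallel to the shaft axis")
    t_cut = (cut_build.normal @ (cut_build.point)) / denom
    t_shoulder = t_cut - stem.seated_depth
    t_tip = t_shoulder - stem.stem_length
    if t_tip < -20.0:
        raise ParameterError("stem is longer than the available canal")
    canal_r_seat = geom.canal_radius(np.array([t_shoulder]))[0]
    r_shoulder = 0.85 * canal_r_seat
    if r_shoulder < 2.0:
        raise ParameterError("canal too narrow to seat a stem")
    if r_shoulder > canal_r_seat:
        raise ParameterError("stem cross-section exceeds canal cross-section "
                             "at the seated depth")
    shoulder = t_shoulder * geom.d
    head_center = shoulder + stem.neck_length * n_stem

    def sd_stem(pts):
        t = pts @ geom.d
        radial = np.linalg.norm(pts - (t[:, None] * geom.d), axis=1)
        frac = np.clip((t_shoulder - t) / stem.stem_length, 0.0, 1.0)
        r = r_shoulder * (1.0 - stem.taper * frac)
        body = radial - r
        body = np.maximum(body, t - t_shoulder)
        body = np.maximum(body, t_tip - t)
        neck = _sd_capsule(pts, shoulder, head_center, 6.0 * p.global_scale)
        head = _sd_sphere(pts, head_center, stem.head_radius)
        return np.minimum(np.minimum(body, _smin(neck, head, 2.0)), body)

    def sd_construct(pts):
        bone = np.maximum(geom.sd_outer(pts),
                          -cut_build.signed_distance(pts))
        return np.minimum(bone, sd_stem(pts))

    bounds = geom.bounds()
    hi = np.maximum(bounds[1], head_center + stem.head_radius + 8.0)
    bounds = np.array([bounds[0], hi])
    mesh = _marching(sd_construct, bounds, p.mesh_resolution)
    rng = np.random.default_rng(rng_seed)
    mesh = _apply_surface_noise(mesh, p.noise_amplitude, rng)
    size = (_occupancy_volume(sd_construct, bounds, TRUTH_VOLUME_PITCH)
            if compute_truth_volume else float("nan"))
    lms = _landmarks(geom, params.side)
    profile = MorphometricProfile(
        nfv_or_pfv=stem.stem_version, varus_valgus=params.varus_valgus,
        neck_shaft_angle=STEM_NSA, size=size,
        head_radius=stem.head_radius / 10.0,
        vfo=(head_center[2] - geom.lt_apex[2]) / 10.0,
        hfo=stem.neck_length * np.sin(np.radians(180.0 - STEM_NSA)) / 10.0,
    )
    plane_out = cut_build
    if params.side == "right":
        mesh = _mirror_y(mesh)
        lms = lms.mirrored_y(new_side="right")
        head_center = head_center.copy()
        head_center[1] *= -1.0
        n_stem = n_stem.copy()
        n_stem[1] *= -1.0
        pt, nm = cut_build.point.copy(), cut_build.normal.copy()
        pt[1] *= -1.0
        nm[1] *= -1.0
        plane_out = OsteotomyPlane(point=pt, normal=nm)
    truth = GroundTruth(params=params, landmarks=lms, profile=profile,
                        head_center=head_center, shaft_axis_point=np.zeros(3),
                        shaft_axis_dir=geom.d.copy(), neck_axis_dir=n_stem,
                        osteotomy_plane=plane_out)
    return mesh, truth


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Sampling specification for a synthetic cohort.

    ``distributions`` maps FemurParams field names to either a fixed value,
    ``("normal", mean, sd)``, ``("uniform", lo, hi)`` or
    ``("quantile_normal", mean, sd)`` — the latter draws the n normal
    quantiles at (i+0.5)/n in seeded random order, a stratified sample
    whose mean/SD match the nominal values almost exactly even at small n
    (used for factor-isolation experiments).  ``side`` may be ``"left"``,
    ``"right"`` or ``"mixed"`` (50/50).  A fixed ``rng_seed`` reproduces
    the identical cohort on re-run.
    """

    n: int
    distributions: dict = field(default_factory=dict)
    side: str = "left"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError("cohort size must be >= 0")
        if self.side not in ("left", "right", "mixed"):
            raise ParameterError(f"bad side policy {self.side!r}")
        valid = {f.name for f in dataclasses.fields(FemurParams)}
        for name, dist in self.distributions.items():
            if name not in valid or name == "side":
                raise ParameterError(f"unknown parameter {name!r}")
            if isinstance(dist, (int, float)):
                continue
            if (not isinstance(dist, (tuple, list)) or len(dist) != 3
                    or dist[0] not in ("normal", "uniform", "fixed",
                                       "quantile_normal")):
                raise ParameterError(f"bad distribution for {name!r}: {dist!r}")
            if dist[0] in ("normal", "quantile_normal") and dist[2] < 0:
                raise ParameterError(f"negative sd for {name!r}")
            if dist[0] == "uniform" and dist[2] < dist[1]:
                raise ParameterError(f"empty uniform range for {name!r}")


def _draw_field(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(dist, (int, float)):
        return np.full(n, float(dist))
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, float(dist[1]))
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=n)
    if kind == "quantile_normal":
        from scipy import stats as _stats
        vals = dist[1] + dist[2] * _stats.norm.ppf((np.arange(n) + 0.5) / n)
        return vals[rng.permutation(n)]
    return rng.uniform(dist[1], dist[2], size=n)


def sample_params(spec: CohortSpec) -> list[FemurParams]:
    """Draw the per-member parameter records (no meshing)."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    columns = {name: _draw_field(spec.distributions[name], spec.n, rng)
               for name in sorted(spec.distributions)}
    if spec.side == "mixed":
        sides = np.where(rng.random(spec.n) < 0.5, "right", "left")
    else:
        sides = np.full(spec.n, spec.side)
    members = []
    for i in range(spec.n):
        kwargs = {name: float(col[i]) for name, col in columns.items()}
        kwargs["side"] = str(sides[i])
        params = dataclasses.replace(FemurParams(), **kwargs)
        params.validate()
        members.append(params)
    return members


def member_seeds(spec: CohortSpec) -> np.ndarray:
    """Deterministic per-member mesh seeds derived from the cohort seed."""
    rng = np.random.default_rng((spec.rng_seed, 0x5EED))
    return rng.integers(0, 2 ** 31, size=spec.n)


def sample_cohort(spec: CohortSpec, compute_truth_volume: bool = True,
                  ) -> list[tuple[trimesh.Trimesh, trimesh.Trimesh, GroundTruth]]:
    """Generate ``spec.n`` independent femora from one seeded generator."""
    members = sample_params(spec)
    seeds = member_seeds(spec)
    return [generate_femur(m, int(s), compute_truth_volume=compute_truth_volume)
            for m, s in zip(members, seeds)]
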