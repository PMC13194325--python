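"""Study orchestration: build the four shape models per cohort, synthesize
±3 SD mode shapes, measure them, label each principal component by its most
prominently changing anatomical feature, and compare native vs prosthetic
femoral version (NFV vs PFV).

The four models per cohort member are

1. native proximal femur,
2. native femur after neck osteotomy (plane cut, capped),
3. intramedullary canal after neck osteotomy (voxel Boolean subtraction of
   the bone shell from the filled osteotomized femur),
4. reconstructed femur (osteotomized femur grouped with the seated stem).

Every stage is deterministic under the study seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from . import __version__
from .anatomy import (LandmarkSet, align_translation_only, build_frame,
                      express_in_frame, mirror_to_left, standardize_length)
from .correspondence import (CorrespondedShape, Template, correspond,
                             make_template)
from .mesh import (MeshError, OccupancyGrid, OsteotomyPlane, as_mesh,
                   boolean_subtract, cut_with_plane, voxelize, write_mesh,
                   write_ply_with_scalar)
from .morphometrics import (FEATURES_BY_KIND, MeasurementError,
                            MorphometricProfile, cut_face_vertex_indices,
                            profile as measure_profile)
from .ssm import ShapeModel, deviation_map, fit_ssm, synthesize, variance_report
from .synthetic import (CohortSpec, FemurParams, StemParams, generate_femur,
                        generate_reconstructed, member_seeds, sample_params)

MODEL_KINDS = ("native", "post_osteotomy", "canal", "reconstructed")

#: human-readable feature labels for PC naming
FEATURE_LABELS = {
    "nfv_or_pfv": "version",
    "neck_cut_version": "version",
    "varus_valgus": "varus/valgus",
    "neck_shaft_angle": "neck-shaft angle",
    "size": "size",
    "head_radius": "head size",
    "vfo": "VFO",
    "hfo": "HFO",
}

#: per-feature normalizer floors: the repeatability scale of each
#: measurement, used when the cohort SD of a feature is negligible.
#: Volume repeatability through the correspondence layer is relative
#: (~2.5% of the shape's size), so its floor scales with the cohort mean.
NORMALIZER_FLOORS = {
    "nfv_or_pfv": 1.0, "neck_cut_version": 1.0, "varus_valgus": 0.5,
    "neck_shaft_angle": 1.0, "size": 3.0, "head_radius": 0.05,
    "vfo": 0.1, "hfo": 0.1,
}
SIZE_FLOOR_FRACTION = 0.025


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything needed to reproduce one cohort study."""

    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n=8))
    stem: StemParams = field(default_factory=StemParams)
    #: "independent" draws stem version from ``stem_version_dist``;
    #: "equal_nfv" seats the stem at the member's native version
    stem_version_policy: str = "independent"
    stem_version_dist: tuple = ("normal", 15.0, 10.0)
    target_length: float = 150.0
    template_points: int = 1200
    correspondence_iterations: int = 3
    correspondence_smooth_weight: float = 0.5
    correspondence_search_radius: float = 20.0
    boolean_pitch: float = 1.0
    n_pcs: int = 3
    model_kinds: tuple = MODEL_KINDS
    alignment_anchor: str = "cut_face_centroid"
    normalizer_overrides: dict = field(default_factory=dict)
    combination_threshold: float = 0.75
    rng_seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.stem.validate()
        if self.n_pcs < 1:
            raise PipelineError("n_pcs must be >= 1")
        if self.stem_version_policy not in ("independent", "equal_nfv"):
            raise PipelineError(
                f"unknown stem version policy {self.stem_version_policy!r}")
        bad = set(self.model_kinds) - set(MODEL_KINDS)
        if bad:
            raise PipelineError(f"unknown model kinds: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortSpec(**raw.pop("cohort", {"n": 8}))
        stem = StemParams(**raw.pop("stem", {}))
        dist = raw.pop("stem_version_dist", ("normal", 15.0, 10.0))
        cfg = cls(cohort=cohort, stem=stem,
                  stem_version_dist=tuple(dist), **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["stem_version_dist"] = list(self.stem_version_dist)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# study result containers
# ---------------------------------------------------------------------------

@dataclass
class KindResult:
    """Per-model-kind artifacts of one study run."""

    kind: str
    model: ShapeModel
    template: Template
    shapes: list[CorrespondedShape]
    member_profiles: list[MorphometricProfile]
    mean_landmarks: LandmarkSet | None
    cut_face_idx: np.ndarray | None  # template vertex ids of the cut face
    head_idx: np.ndarray | None = None  # template vertex ids on the head
    lt_idx: np.ndarray | None = None    # template vertex ids near the LT apex
    shaft_slabs: list | None = None     # frozen slab index groups (mean shape)


@dataclass
class StudyResult:
    config: StudyConfig
    kinds: dict[str, KindResult]
    member_params: list[FemurParams]
    nfv_measured: np.ndarray
    pfv_measured: np.ndarray


@dataclass
class PCLabel:
    model_kind: str
    pc_index: int                 # 0-based
    feature_values: dict          # name -> (minus3, mean, plus3)
    change_scores: dict           # name -> normalized |f(+3) - f(-3)|
    primary: str
    combination: list[str]

    def to_dict(self) -> dict:
        return {"model_kind": self.model_kind, "pc_index": self.pc_index,
                "feature_values": {k: list(v) for k, v in
                                   self.feature_values.items()},
                "change_scores": self.change_scores,
                "primary": self.primary, "combination": self.combination}


# ---------------------------------------------------------------------------
# per-member model construction
# ---------------------------------------------------------------------------

def _prepare_member(params: FemurParams, stem: StemParams,
                    stem_version: float, seed: int, config: StudyConfig,
                    ) -> dict:
    """Generate and standardize the four meshes of one cohort member.

    Returns frame-expressed, mirrored-to-left, length-standardized meshes
    plus the landmarks and osteotomy plane in the same coordinates.
    """
    kinds = config.model_kinds
    outer, canal, truth = generate_femur(params, seed,
                                         compute_truth_volume=False)
    lms = truth.landmarks
    frame = build_frame(lms)
    outer, lms_f, _ = express_in_frame(outer, lms, frame)
    canal, _, _ = express_in_frame(canal, lms, frame)
    plane = OsteotomyPlane(
        point=frame.to_frame(truth.osteotomy_plane.point)[0],
        normal=truth.osteotomy_plane.normal @ frame.rotation().T)
    recon = t4hc = None
    if "reconstructed" in kinds:
        stem_i = dataclasses.replace(stem, stem_version=stem_version)
        recon, truth4 = generate_reconstructed(
            params, stem_i, cut=truth.osteotomy_plane, rng_seed=seed,
            compute_truth_volume=False)
        recon, _, _ = express_in_frame(recon, lms, frame)
        t4hc = frame.to_frame(truth4.head_center)[0]
    if lms_f.side == "right":
        outer, lms_left = mirror_to_left(outer, lms_f)
        canal, _ = mirror_to_left(canal, lms_f)
        if recon is not None:
            recon, _ = mirror_to_left(recon, lms_f)
            t4hc = t4hc * np.array([1.0, -1.0, 1.0])
        lms_f = lms_left
        flip = np.array([1.0, -1.0, 1.0])
        plane = OsteotomyPlane(point=plane.point * flip,
                               normal=plane.normal * flip)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = {"native": outer, "reconstructed": recon}
        if "post_osteotomy" in kinds or "canal" in kinds:
            # model 2: simulated neck osteotomy
            m2 = cut_with_plane(outer, plane, cap=True)
            raw["post_osteotomy"] = m2
            if "canal" in kinds:
                # model 3: Boolean subtraction of the bone shell from the
                # filled osteotomized femur leaves the intramedullary cavity
                b = np.array(m2.bounds)
                b[0] -= 2.0
                b[1] += 2.0
                occ_filled = voxelize(m2, config.boolean_pitch, bounds=b)
                occ_canal = voxelize(canal, config.boolean_pitch, bounds=b)
                shell = OccupancyGrid(occ_filled.origin, occ_filled.pitch,
                                      occ_filled.occupancy
                                      & ~occ_canal.occupancy)
                m3 = boolean_subtract(occ_filled, shell)
                if m3 is None:
                    raise PipelineError("member has no intramedullary cavity")
                raw["canal"] = m3
        meshes = {kind: standardize_length(raw[kind], config.target_length)
                  for kind in kinds}
    return {"meshes": meshes, "landmarks": lms_f, "plane": plane,
            "truth": truth, "recon_head_seed": t4hc,
            "stem_version": stem_version}


def _measure_member(kind: str, mesh, member: dict,
                    offset: np.ndarray) -> MorphometricProfile:
    lms = member["landmarks"].translated(offset)
    if kind == "reconstructed":
        lms = LandmarkSet(dict(lms.points), side=lms.side)
        lms.points["head_seed"] = member["recon_head_seed"] + offset
    plane = member["plane"]
    plane = OsteotomyPlane(point=plane.point + offset, normal=plane.normal)
    return measure_profile(mesh, lms, kind, cut_plane=plane)


def run_four_models(config: StudyConfig, progress: bool = False,
                    ) -> StudyResult:
    """Execute the full study for one cohort.

    For every member the four meshes are generated, standardized, mirrored
    (rights) and aligned; each model kind is then corresponded to its own
    template and a PCA shape model is fitted.  Per-member morphometric
    profiles are measured on the aligned meshes (they normalize the PC
    change scores), and NFV/PFV are recorded for the version comparison.
    """
    config.validate()
    params = sample_params(config.cohort)
    seeds = member_seeds(config.cohort)
    rng = np.random.default_rng((config.rng_seed, 0xD1CE))
    members = []
    for i, (p, s) in enumerate(zip(params, seeds)):
        if config.stem_version_policy == "equal_nfv":
            sv = p.version
        else:
            kind, m, sd = config.stem_version_dist
            sv = float(rng.normal(m, sd)) if kind == "normal" else float(m)
        try:
            members.append(_prepare_member(p, config.stem, sv, int(s), config))
        except (MeshError, MeasurementError, ValueError) as exc:
            raise PipelineError(f"member {i} failed at preparation: {exc}") \
                from exc
    kinds: dict[str, KindResult] = {}
    nfv = np.full(len(members), np.nan)
    pfv = np.full(len(members), np.nan)
    for kind in config.model_kinds:
        meshes = [m["meshes"][kind] for m in members]
        aligned, offsets = align_translation_only(
            meshes, [m["landmarks"] for m in members],
            anchor=config.alignment_anchor)
        profiles = []
        for i, (mesh, member, off) in enumerate(
                zip(aligned, members, offsets)):
            try:
                prof = _measure_member(kind, mesh, member, off)
            except (MeshError, MeasurementError) as exc:
                raise PipelineError(
                    f"member {i} failed at {kind} measurement: {exc}") from exc
            profiles.append(prof)
            if kind == "native":
                nfv[i] = prof.nfv_or_pfv
            elif kind == "reconstructed":
                pfv[i] = prof.nfv_or_pfv
        template = make_template(aligned, config.template_points)
        # anatomical initialization: matched landmark arrays drive a TPS
        # warp of the template onto each target before projection, so the
        # head/neck correspondence follows femoral torsion
        lm_names = ("head_seed", "gt_tip", "lt_apex",
                    "intertrochanteric_crest", "condyle_posterior_medial",
                    "condyle_posterior_lateral")

        def _lm_array(i):
            if kind not in ("native", "reconstructed"):
                return None
            pts = []
            for name in lm_names:
                p = members[i]["landmarks"].points[name] + offsets[i]
                if kind == "reconstructed" and name == "head_seed":
                    p = members[i]["recon_head_seed"] + offsets[i]
                pts.append(p)
            # shared anchors pin the warp along the version-invariant
            # distal shaft (the cut-face centroid is at the origin after
            # alignment), preventing the head displacement from bowing it
            pts.extend([[0.0, 0.0, 0.0], [0.0, 0.0, 35.0],
                        [0.0, 0.0, 70.0]])
            return np.array(pts)

        tpl_member = int(template.template_id.split("_")[1])
        src_lms = _lm_array(tpl_member)
        shapes = []
        for i, mesh in enumerate(aligned):
            try:
                shapes.append(correspond(
                    template, mesh,
                    iterations=config.correspondence_iterations,
                    smooth_weight=config.correspondence_smooth_weight,
                    search_radius=config.correspondence_search_radius,
                    source_landmarks=src_lms,
                    target_landmarks=_lm_array(i)))
            except Exception as exc:
                raise PipelineError(
                    f"member {i} failed at {kind} correspondence: {exc}") \
                    from exc
        model = fit_ssm(shapes, template_id=template.template_id)
        model.metadata["kind"] = kind
        # cut-face vertex ids on the template support the surrogate-version
        # measurement on synthesized shapes, whose averaged cut face is only
        # approximately planar
        cut_idx = None
        if kind in ("post_osteotomy", "canal"):
            pick = int(template.template_id.split("_")[1])
            plane = members[pick]["plane"]
            plane = OsteotomyPlane(point=plane.point + offsets[pick],
                                   normal=plane.normal)
            try:
                cut_idx = cut_face_vertex_indices(
                    template.mesh, plane, angle_tol_deg=12.0, dist_tol=2.0)
            except MeasurementError:
                cut_idx = None
        # mean landmarks seed measurements on synthesized shapes
        pts_mean = {}
        for name in members[0]["landmarks"].points:
            pts_mean[name] = np.mean(
                [m["landmarks"].points[name] + off
                 for m, off in zip(members, offsets)], axis=0)
        if kind == "reconstructed":
            pts_mean["head_seed"] = np.mean(
                [m["recon_head_seed"] + off
                 for m, off in zip(members, offsets)], axis=0)
        # landmark tracking through the correspondence: head-region vertex
        # set and LT-apex vertex follow the shape under mode deformation,
        # so ±3 SD shapes can be measured with moving seeds
        mean_pts = model.mean.reshape(-1, 3)
        from .morphometrics import shaft_slab_groups
        # conservative distal fraction keeps the frozen slabs clear of the
        # lesser-trochanter bump on length-standardized femora
        shaft_slabs = shaft_slab_groups(mean_pts, distal_fraction=0.30)
        head_idx = lt_idx = None
        if kind in ("native", "reconstructed"):
            # select only the spherical cap: radius barely beyond the
            # measured head radius, so the strongly-rotating neck blend
            # does not contaminate the tracked sphere fit
            radii = [p.head_radius for p in profiles
                     if p.available("head_radius")]
            r_head = 10.0 * float(np.mean(radii)) if radii else \
                (23.0 if kind == "native" else 16.0)
            r_sel = 1.08 * r_head
            head_idx = np.nonzero(np.linalg.norm(
                mean_pts - pts_mean["head_seed"], axis=1) < r_sel)[0]
            if len(head_idx) < 10:
                head_idx = None
            lt_d = np.linalg.norm(mean_pts - pts_mean["lt_apex"], axis=1)
            lt_idx = np.nonzero(lt_d < 6.0)[0]
            if len(lt_idx) == 0:
                lt_idx = np.array([int(np.argmin(lt_d))])
        kinds[kind] = KindResult(
            kind=kind, model=model, template=template, shapes=shapes,
            member_profiles=profiles,
            mean_landmarks=LandmarkSet(pts_mean, side="left"),
            cut_face_idx=cut_idx, head_idx=head_idx, lt_idx=lt_idx,
            shaft_slabs=shaft_slabs)
    return StudyResult(config=config, kinds=kinds, member_params=params,
                       nfv_measured=nfv, pfv_measured=pfv)


# ---------------------------------------------------------------------------
# PC labelling
# ---------------------------------------------------------------------------

def feature_normalizers(profiles: list[MorphometricProfile], kind: str,
                        overrides: dict | None = None) -> dict:
    """Cohort SD of each applicable feature, floored at the measurement's
    repeatability scale; config overrides win."""
    out = {}
    for name in FEATURES_BY_KIND[kind]:
        vals = [getattr(p, name) for p in profiles if p.available(name)]
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else 0.0
        floor = NORMALIZER_FLOORS[name]
        if name == "size" and vals:
            floor = max(floor, SIZE_FLOOR_FRACTION * float(np.mean(vals)))
        out[name] = max(sd, floor)
    if overrides:
        out.update({k: float(v) for k, v in overrides.items() if k in out})
    return out


def score_features(feature_triples: dict, normalizers: dict,
                   combination_threshold: float = 0.75,
                   ) -> tuple[dict, str, list[str]]:
    """Change scores and labels from (−3SD, mean, +3SD) feature triples.

    Score = |f(+3SD) − f(−3SD)| / normalizer.  The primary label is the
    top-scoring feature's label; features scoring at least
    ``combination_threshold`` of the maximum form the combination (ties are
    ordered deterministically by score then label name).
    """
    scores = {name: abs(t[2] - t[0]) / normalizers[name]
              for name, t in feature_triples.items()}
    if not scores or max(scores.values()) <= 0:
        return scores, "none", []
    smax = max(scores.values())
    combo_feats = sorted(
        [n for n, s in scores.items() if s >= combination_threshold * smax],
        key=lambda n: (-scores[n], FEATURE_LABELS[n]))
    primary = FEATURE_LABELS[combo_feats[0]]
    combo = sorted({FEATURE_LABELS[n] for n in combo_feats})
    return scores, primary, combo


def measure_synthesized(kres: KindResult, points: np.ndarray,
                        ) -> MorphometricProfile:
    """Morphometric profile of a synthesized (corresponded) shape.

    The mesh is rebuilt on the template topology; the head sphere is fitted
    to the tracked head vertex set and the LT apex taken as the tracked LT
    patch centroid, so both the selections and the seeds stay fixed in
    index space and follow the shape wherever the mode deformation moves
    it."""
    from .morphometrics import fit_sphere_to_indexed, shaft_axis_from_groups
    mesh = as_mesh(points, kres.template.mesh.faces)
    if mesh.volume < 0:
        mesh.invert()
    lms = LandmarkSet(dict(kres.mean_landmarks.points),
                      side=kres.mean_landmarks.side)
    head_fit = None
    if kres.head_idx is not None:
        head_fit = fit_sphere_to_indexed(points[kres.head_idx])
        lms.points["head_seed"] = head_fit[0]
    if kres.lt_idx is not None:
        lms.points["lt_apex"] = points[kres.lt_idx].mean(axis=0)
    shaft_fit = None
    if kres.shaft_slabs is not None:
        shaft_fit = shaft_axis_from_groups(points, kres.shaft_slabs)
    return measure_profile(mesh, lms, kres.kind,
                           cut_face_indices=kres.cut_face_idx,
                           head_fit=head_fit, shaft_fit=shaft_fit)


def label_pcs(result_or_kind: StudyResult | KindResult,
              model_kind: str | None = None, k: int = 3,
              normalizer_overrides: dict | None = None,
              combination_threshold: float = 0.75) -> list[PCLabel]:
    """Label the first ``k`` PCs by their most prominently changing feature.

    For each PC the shapes at −3 SD, mean and +3 SD are synthesized and
    measured; each feature's change score is |f(+3SD) − f(−3SD)| divided by
    its cohort-SD normalizer.  The primary label is the top-scoring feature;
    features scoring at least ``combination_threshold`` of the maximum are
    reported together as a combination.
    """
    if isinstance(result_or_kind, StudyResult):
        if model_kind is None:
            raise PipelineError("model_kind required with a StudyResult")
        kres = result_or_kind.kinds[model_kind]
        overrides = normalizer_overrides or \
            result_or_kind.config.normalizer_overrides
        combination_threshold = result_or_kind.config.combination_threshold
    else:
        kres = result_or_kind
        overrides = normalizer_overrides
    if kres.model.n_modes < k:
        raise PipelineError(f"model has {kres.model.n_modes} modes < k={k}")
    normalizers = feature_normalizers(kres.member_profiles, kres.kind,
                                      overrides)
    mean_prof = measure_synthesized(kres, synthesize(
        kres.model, np.zeros(kres.model.n_modes)).points)
    labels = []
    for pc in range(k):
        plus = measure_synthesized(
            kres, synthesize(kres.model, {pc: +3.0}).points)
        minus = measure_synthesized(
            kres, synthesize(kres.model, {pc: -3.0}).points)
        values = {}
        for name in FEATURES_BY_KIND[kres.kind]:
            triple = (getattr(minus, name), getattr(mean_prof, name),
                      getattr(plus, name))
            if any(v is None for v in triple):
                continue
            values[name] = triple
        scores, primary, combo = score_features(values, normalizers,
                                                combination_threshold)
        labels.append(PCLabel(
            model_kind=kres.kind, pc_index=pc, feature_values=values,
            change_scores={n: float(s) for n, s in scores.items()},
            primary=primary, combination=combo))
    return labels


# ---------------------------------------------------------------------------
# NFV vs PFV comparison
# ---------------------------------------------------------------------------

@dataclass
class VersionComparison:
    n: int
    mean_nfv: float
    sd_nfv: float
    mean_pfv: float
    sd_pfv: float
    mean_abs_diff: float
    sd_abs_diff: float
    t_p_value: float | None
    permutation_p_value: float | None
    pearson_r: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_versions(nfv, pfv, paired: bool = True,
                     n_permutations: int = 10000,
                     rng_seed: int = 0) -> VersionComparison:
    """Summarize two version series and test their paired difference.

    Returns mean±SD of each series and of |NFV−PFV|, the paired two-sided
    t-test p-value, a seeded sign-flip permutation p-value as a
    distribution-free cross-check, and the Pearson correlation.
    """
    nfv = np.asarray(nfv, dtype=np.float64)
    pfv = np.asarray(pfv, dtype=np.float64)
    if paired and len(nfv) != len(pfv):
        raise ValueError(f"paired series differ in length: "
                         f"{len(nfv)} vs {len(pfv)}")
    if paired and len(nfv) < 2:
        raise ValueError("paired comparison needs >= 2 pairs")
    out = dict(n=len(nfv),
               mean_nfv=float(nfv.mean()), sd_nfv=float(nfv.std(ddof=1)),
               mean_pfv=float(pfv.mean()), sd_pfv=float(pfv.std(ddof=1)))
    if paired:
        diff = nfv - pfv
        adiff = np.abs(diff)
        out["mean_abs_diff"] = float(adiff.mean())
        out["sd_abs_diff"] = float(adiff.std(ddof=1))
        if np.allclose(diff, diff[0]) and abs(diff[0]) < 1e-12:
            t_p = 1.0
        elif np.allclose(diff, diff.mean()):
            t_p = 0.0  # constant nonzero shift: zero variance, exact effect
        else:
            t_p = float(stats.ttest_rel(nfv, pfv).pvalue)
        rng = np.random.default_rng(rng_seed)
        observed = abs(diff.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(diff)))
        perm = np.abs((signs * diff).mean(axis=1))
        perm_p = float((np.sum(perm >= observed - 1e-12) + 1)
                       / (n_permutations + 1))
        out["t_p_value"] = t_p
        out["permutation_p_value"] = perm_p
        if nfv.std() > 0 and pfv.std() > 0:
            out["pearson_r"] = float(stats.pearsonr(nfv, pfv).statistic)
        else:
            out["pearson_r"] = None
    else:
        out.update(mean_abs_diff=float("nan"), sd_abs_diff=float("nan"),
                   t_p_value=None, permutation_p_value=None, pearson_r=None)
    return VersionComparison(**out)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _fmt(value, decimals=0) -> str:
    if value is None:
        return "----"
    return f"{value:.{decimals}f}"


def report(result: StudyResult, outdir, k: int | None = None) -> dict:
    """Write the study artifacts: variance tables, a feature table in the
    −3SD/mean/+3SD layout ('----' for unavailable features), ±3 SD STL
    exports and deviation-map CSVs per PC, PC-label JSON and a run manifest.
    Re-running on unchanged artifacts overwrites files with identical
    content.  Returns the paths written."""
    import h5py
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = k or result.config.n_pcs
    written = {}
    all_labels = {}
    rows = []
    kinds_present = [kk for kk in MODEL_KINDS if kk in result.kinds]
    for kind in kinds_present:
        kres = result.kinds[kind]
        kk = min(k, kres.model.n_modes)
        rep = variance_report(kres.model, kk)
        vpath = outdir / f"variance_{kind}.csv"
        with open(vpath, "w") as fh:
            fh.write("pc,percent,cumulative_percent\n")
            for i in range(kk):
                fh.write(f"{i + 1},{rep['per_mode_percent'][i]},"
                         f"{rep['cumulative_percent'][i]}\n")
        written[f"variance_{kind}"] = vpath
        labels = label_pcs(result, kind, k=kk)
        all_labels[kind] = [lab.to_dict() for lab in labels]
        for lab in labels:
            for name, (lo, mid, hi) in lab.feature_values.items():
                rows.append({"model": kind, "pc": lab.pc_index + 1,
                             "feature": name, "minus3sd": _fmt(lo),
                             "mean": _fmt(mid), "plus3sd": _fmt(hi)})
            # flag the features this model kind never measures
            for name in MorphometricProfile.feature_names():
                if name not in lab.feature_values and \
                        name in FEATURE_LABELS:
                    applicable = name in FEATURES_BY_KIND[kind]
                    if not applicable:
                        rows.append({"model": kind, "pc": lab.pc_index + 1,
                                     "feature": name, "minus3sd": "----",
                                     "mean": "----", "plus3sd": "----"})
        for lab in labels:
            for sd, wname in ((-3.0, "minus3sd"), (3.0, "plus3sd")):
                shp = synthesize(kres.model, {lab.pc_index: sd})
                mesh = as_mesh(shp.points, kres.template.mesh.faces)
                if mesh.volume < 0:
                    mesh.invert()
                mpath = outdir / f"{kind}_pc{lab.pc_index + 1}_{wname}.stl"
                write_mesh(mesh, mpath, "stl")
                written[mpath.stem] = mpath
            dev = deviation_map(kres.model,
                                synthesize(kres.model, {lab.pc_index: 3.0}),
                                kres.template.mesh.faces)
            dpath = outdir / f"{kind}_pc{lab.pc_index + 1}_deviation.csv"
            np.savetxt(dpath, dev, fmt="%.4f", header="deviation_mm",
                       comments="")
            written[dpath.stem] = dpath
            mean_mesh = as_mesh(kres.model.mean.reshape(-1, 3),
                                kres.template.mesh.faces)
            ppath = outdir / f"{kind}_pc{lab.pc_index + 1}_deviation.ply"
            write_ply_with_scalar(mean_mesh, dev, ppath)
            written[ppath.stem + "_ply"] = ppath
    import pandas as pd
    table = pd.DataFrame(rows)
    tpath = outdir / "feature_table.csv"
    table.to_csv(tpath, index=False)
    written["feature_table"] = tpath
    lpath = outdir / "pc_labels.json"
    with open(lpath, "w") as fh:
        json.dump(all_labels, fh, indent=1, sort_keys=True)
    written["pc_labels"] = lpath
    hpath = outdir / "models.h5"
    with h5py.File(hpath, "w", track_order=False) as fh:
        for kind in kinds_present:
            grp = fh.create_group(kind)
            result.kinds[kind].model.to_hdf5(grp)
    written["models"] = hpath
    manifest = {
        "package_version": __version__,
        "seed": result.config.rng_seed,
        "cohort_seed": result.config.cohort.rng_seed,
        "n_members": result.config.cohort.n,
        "n_pcs": k,
        "template_points": result.config.template_points,
        "boolean_pitch": result.config.boolean_pitch,
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    written["manifest"] = mpath
    return written
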